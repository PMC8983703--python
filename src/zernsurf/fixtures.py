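"""Synthetic inputs with known ground truth.

Everything downstream (surfaces, descriptors, the pair network, domain
extraction, class assignment) is exercised on inputs generated here, so the
whole toolkit is testable without downloading any structure database. The
generators are pure functions of their parameters and seed: regeneration is
bit-identical.

Three families:

* idealized protein backbones (alpha-helix, antiparallel beta-sheet, compact
  random blob) emitted as :class:`~zernsurf.structure_io.Structure` objects
  with N/CA/C/O atoms, so both atom-selection modes work;
* descriptor clusters — synthetic stand-ins for fold families in descriptor
  space, with controllable between-fold separation and within-fold noise;
* piecewise-constant pLDDT profiles for the domain-extraction rules.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .structure_io import Atom, ConfidenceProfile, Structure
from .zernike import ZernikeDescriptor, descriptor_length

__all__ = [
    "make_ideal_helix",
    "make_ideal_sheet",
    "make_blob_protein",
    "make_descriptor_clusters",
    "make_plddt_profile",
    "make",
]

# cylindrical backbone offsets (radius A, phase deg, rise A) for an ideal
# alpha-helix: 1.5 A rise and 100 degrees twist per residue
_HELIX_OFFSETS = {
    "N": (1.58, -28.0, -0.90),
    "CA": (2.28, 0.0, 0.0),
    "C": (1.67, 26.0, 0.45),
    "O": (2.00, 25.0, 1.65),
}
_RISE = 1.5
_TWIST = 100.0


def _backbone_from_ca(
    ca: np.ndarray, chain_id: str = "A", bfactor: float = 90.0
) -> list[Atom]:
    """Place approximate N/C/O atoms around a CA trace.

    N sits a third of the way back toward the previous CA, C a third of the
    way toward the next, each nudged off the CA-CA axis so the atoms are not
    collinear. Good enough for surface generation and atom-count tests; not
    stereochemically exact.
    """
    n_res = len(ca)
    atoms: list[Atom] = []
    for i in range(n_res):
        prev_dir = ca[i] - ca[i - 1] if i > 0 else ca[min(i + 1, n_res - 1)] - ca[i]
        next_dir = ca[min(i + 1, n_res - 1)] - ca[i] if i < n_res - 1 else prev_dir
        perp = np.cross(prev_dir, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.array([0.0, 1.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        n_pos = ca[i] - prev_dir / 3.0 + 0.4 * perp
        c_pos = ca[i] + next_dir / 3.0 - 0.4 * perp
        o_pos = c_pos + 1.23 * perp
        for name, el, pos in (
            ("N", "N", n_pos),
            ("CA", "C", ca[i]),
            ("C", "C", c_pos),
            ("O", "O", o_pos),
        ):
            atoms.append(
                Atom(
                    element=el,
                    name=name,
                    coord=tuple(float(x) for x in pos),
                    residue_index=i + 1,
                    chain_id=chain_id,
                    bfactor=bfactor,
                )
            )
    return atoms


def make_ideal_helix(n_residues: int, seed: int = 0, jitter: float = 0.0) -> Structure:
    """Poly-alanine backbone on an ideal alpha-helix.

    Rise 1.5 A and twist 100 degrees per residue, which puts consecutive CA
    atoms 3.8 A apart. ``jitter`` adds seeded isotropic Gaussian noise (A)
    to every coordinate; with jitter 0 the output is independent of seed.
    """
    if n_residues < 5:
        raise ValueError("a helix fixture needs at least 5 residues")
    atoms: list[Atom] = []
    rng = np.random.default_rng(seed)
    for i in range(n_residues):
        base = math.radians(_TWIST * i)
        for name, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            r, dphi, dz = _HELIX_OFFSETS[name]
            phi = base + math.radians(dphi)
            pos = np.array([r * math.cos(phi), r * math.sin(phi), _RISE * i + dz])
            if jitter > 0:
                pos = pos + rng.normal(0.0, jitter, 3)
            atoms.append(
                Atom(
                    element=el,
                    name=name,
                    coord=tuple(float(x) for x in pos),
                    residue_index=i + 1,
                    chain_id="A",
                    bfactor=90.0,
                )
            )
    return Structure(id=f"helix{n_residues}", atoms=atoms)


def make_ideal_sheet(
    n_strands: int = 2,
    strand_len: int = 8,
    seed: int = 0,
    jitter: float = 0.0,
) -> Structure:
    """Antiparallel beta-sheet: extended strands 4.8 A apart with a pleat.

    CA atoms advance 3.3 A along the strand with an alternating 0.6 A pleat,
    giving the extended i to i+2 distance of about 6.6 A that strand
    geometry detectors look for.
    """
    if n_strands < 1 or strand_len < 3:
        raise ValueError("need >= 1 strand of >= 3 residues")
    rng = np.random.default_rng(seed)
    ca: list[np.ndarray] = []
    for s in range(n_strands):
        direction = 1 if s % 2 == 0 else -1
        xs = np.arange(strand_len) * 3.3
        if direction < 0:
            xs = xs[::-1]
        for i in range(strand_len):
            ca.append(np.array([xs[i], 4.8 * s, 0.6 * ((i + s) % 2)]))
    ca_arr = np.array(ca)
    if jitter > 0:
        ca_arr = ca_arr + rng.normal(0.0, jitter, ca_arr.shape)
    return Structure(
        id=f"sheet{n_strands}x{strand_len}", atoms=_backbone_from_ca(ca_arr)
    )


def make_blob_protein(n_residues: int = 40, seed: int = 0) -> Structure:
    """Compact self-avoiding CA random walk with 3.8 A steps.

    Steps are biased back toward the centroid so the chain stays globular;
    a crude globule whose surface has no secondary-structure regularity.
    """
    if n_residues < 5:
        raise ValueError("need at least 5 residues")
    rng = np.random.default_rng(seed)
    ca = [np.zeros(3)]
    for _ in range(n_residues - 1):
        for _attempt in range(200):
            step = rng.normal(size=3)
            step /= np.linalg.norm(step)
            centroid = np.mean(ca, axis=0)
            pull = centroid - ca[-1]
            norm_pull = np.linalg.norm(pull)
            if norm_pull > 1e-9:
                step = 0.7 * step + 0.3 * pull / norm_pull
                step /= np.linalg.norm(step)
            cand = ca[-1] + 3.8 * step
            dists = np.linalg.norm(np.array(ca) - cand, axis=1)
            if dists.min() > 3.0:
                break
        ca.append(cand)
    return Structure(id=f"blob{n_residues}", atoms=_backbone_from_ca(np.array(ca)))


def make_descriptor_clusters(
    n_folds: int = 10,
    per_fold: int = 20,
    dim: int = 121,
    separation: float = 1.0,
    noise: float = 0.15,
    seed: int = 0,
) -> tuple[list[ZernikeDescriptor], list[str]]:
    """Labeled synthetic fold clusters in descriptor space.

    Fold centers are drawn uniformly on the non-negative part of a sphere of
    radius ``separation``; members add half-normal noise of scale ``noise``
    per component (descriptor entries are norms, hence non-negative). Each
    fold also carries characteristic mesh vertex/face counts, jittered per
    member, so the pair-feature slots for surface size are informative.
    """
    if separation <= 0 or noise < 0:
        raise ValueError("separation must be > 0 and noise >= 0")
    rng = np.random.default_rng(seed)
    order = _matching_order(dim)
    descriptors: list[ZernikeDescriptor] = []
    labels: list[str] = []
    for f in range(n_folds):
        center = np.abs(rng.normal(size=dim))
        center *= separation / np.linalg.norm(center)
        base_v = int(rng.integers(500, 5000))
        base_f = 2 * base_v - 4
        for j in range(per_fold):
            values = np.clip(center + np.abs(rng.normal(0.0, noise, dim)), 0.0, None)
            nv = base_v + int(rng.integers(-20, 21))
            descriptors.append(
                ZernikeDescriptor(
                    order=order,
                    values=values,
                    source_mode="synthetic",
                    mesh_vertices=nv,
                    mesh_faces=2 * nv - 4,
                )
            )
            labels.append(f"f.{f}")
    return descriptors, labels


def _matching_order(dim: int) -> int:
    for order in range(0, 101):
        if descriptor_length(order) == dim:
            return order
    raise ValueError(f"{dim} is not a valid descriptor length")


def make_plddt_profile(
    layout: Sequence[tuple[int, float]], seed: int = 0, jitter: float = 0.0
) -> ConfidenceProfile:
    """Piecewise-constant pLDDT profile from (run_length, level) segments.

    ``jitter`` adds seeded noise that is clipped so no value crosses the
    70.0 confidence boundary — the confident/non-confident status of every
    residue is exactly the layout's. A level of exactly 70.0 is rejected
    because its status under a strict > threshold would be ambiguous.
    """
    rng = np.random.default_rng(seed)
    chunks: list[np.ndarray] = []
    for run_length, level in layout:
        if run_length < 1:
            raise ValueError("run lengths must be >= 1")
        if not 0 <= level <= 100:
            raise ValueError("pLDDT levels must lie in [0, 100]")
        if level == 70.0:
            raise ValueError(
                "level 70.0 sits exactly on the confidence threshold; "
                "use a value strictly above or below it"
            )
        vals = np.full(run_length, float(level))
        if jitter > 0:
            vals = vals + rng.normal(0.0, jitter, run_length)
            if level > 70.0:
                vals = np.clip(vals, 70.0 + 1e-6, 100.0)
            else:
                vals = np.clip(vals, 0.0, 70.0)
        chunks.append(vals)
    if not chunks:
        raise ValueError("layout is empty")
    return ConfidenceProfile(values=np.concatenate(chunks))


def make(kind: str, seed: int = 0, **params) -> object:
    """Dispatcher used by the command-line ``fixtures make`` subcommand."""
    makers = {
        "helix": make_ideal_helix,
        "sheet": make_ideal_sheet,
        "blob": make_blob_protein,
        "clusters": make_descriptor_clusters,
        "plddt": make_plddt_profile,
    }
    if kind not in makers:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {sorted(makers)}")
    return makers[kind](seed=seed, **params)
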