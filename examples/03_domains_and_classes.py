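"""Confident-domain extraction and secondary-structure class assignment.

Builds a synthetic pLDDT profile with two confident stretches separated by
a short low-confidence gap, extracts confident domains with the
run/length/gap rules, and assigns secondary-structure classes to ideal
helix and sheet fixtures with the expert rule cascade.
"""

from zernsurf.classify import assign_class_rule, ss_content_from_structure
from zernsurf.domains import extract_confident_domains
from zernsurf.fixtures import make_ideal_helix, make_ideal_sheet, make_plddt_profile

profile = make_plddt_profile([(60, 90.0), (5, 40.0), (60, 90.0), (30, 45.0)])
print(f"profile: {len(profile)} residues "
      "(60 confident, 5 low, 60 confident, 30 low)")
for region in extract_confident_domains(profile):
    print(f"  confident domain {region.start}-{region.end} "
          f"({region.n_confident} confident residues, "
          f"mean pLDDT {region.mean_plddt:.1f})")
print("(the 5-residue gap is merged; runs must exceed 50 residues to count)")

for s in (make_ideal_helix(80), make_ideal_sheet(5, 12)):
    content = ss_content_from_structure(s)
    label = assign_class_rule(content, rule="original")
    print(f"{s.id}: length {content.length}, helix {content.helix_frac:.0%}, "
          f"sheet {content.sheet_frac:.0%} -> class {label}")
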