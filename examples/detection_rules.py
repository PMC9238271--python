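"""Calling EntF* present or absent in chromatographic features.

Low-resolution MRM features are judged on retention time, the
quantifier/qualifier area ratio (2.0-4.0), signal-to-noise (> 3), and
for serum a concentration above the 100 pM LOQ.  High-resolution
features are judged on matched daughter ions and precursor isotope
peaks within the instrument's m/z tolerance.  Every violated rule is
named, so a negative verdict is auditable.
"""

import dataclasses

from entfkit import detection
from entfkit.synthetic import _entfstar_reference_ions, gen_chrom_records

good = gen_chrom_records(seed=0, n=1, method="LC1MS1")[0]
print("all-pass MRM feature:", detection.classify_lowres(good))

low_conc = dataclasses.replace(good, concentration_pm=80.0)
bad_ratio = dataclasses.replace(good, quantifier_area=5 * good.qualifier_area)
for rec in (low_conc, bad_ratio):
    res = detection.classify_lowres(rec)
    print(f"violation -> positive={res.positive}, "
          f"failed rules={sorted(res.failed_rules)}")

daughters, isotopes = _entfstar_reference_ions()
hr = gen_chrom_records(seed=0, n=1, method="LC1MS3")[0]
res = detection.classify_highres(hr, reference_daughters=daughters,
                                 reference_isotopes=isotopes)
print(f"\nOrbitrap feature: positive={res.positive} "
      f"(needs >=2 daughters and >=4 isotope peaks within 0.005 Th)")

print("\nSerum summary with below-LOQ values counted as zero:")
mean, sem, n, n_above = detection.summarize_serum(
    [150.0, 40.0, 0.0, 650.0, 90.0, 210.0], loq=100.0)
print(f"mean {mean:.0f} pM (SEM {sem:.0f}), {n_above}/{n} samples above LOQ")
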