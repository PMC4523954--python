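"""HLA-DQ heterodimer typing and the two haplotype-based risk scores.

Types a few DQ genotypes: the risk code is 0 (low: no risk heterodimer),
1 (medium: a single DQ2.5-het, DQ2.2 or DQ8), or 2 (high: DQ2.5-hom, or
DQ2.5-het together with DQ2.2); the zygosity is the DQ2.5 copy number.
"""

import pandas as pd

from hlagrs.hla import type_cohort

genotypes = pd.DataFrame(
    {
        "IID": ["hom", "het", "het+dq22", "dq8", "none"],
        "DQA1_1": ["05:01", "05:01", "05:01", "03:01", "01:01"],
        "DQA1_2": ["05:01", "01:01", "02:01", "01:01", "01:02"],
        "DQB1_1": ["02:01", "02:01", "02:01", "03:02", "05:01"],
        "DQB1_2": ["02:01", "05:01", "02:02", "05:01", "06:02"],
    }
)
profiles = type_cohort(genotypes)
print(profiles.to_string(index=False))
print("\nrisk_code 2 marks the highest-risk genotypes (DQ2.5-hom, DQ2.5-het+DQ2.2);")
print("zygosity counts DQ2.5 copies (0/1/2) and drives the gene-dose risk gradient.")
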