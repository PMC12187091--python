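"""AUC-based minimum sample size for an external test cohort.

Hanley-McNeil variance approximation: smallest N whose two-sided alpha 0.05
test of AUC = 0.5 against the alternative AUC = 0.8 reaches 90% power, with
responders making up 70% of the cohort.
"""

from radpath.response import auc_sample_size

n = auc_sample_size(auc_alt=0.80, auc_null=0.50, power=0.90,
                    alpha=0.05, prevalence=0.70)
print(f"minimum external-test cohort size: {n} patients")

for power in (0.80, 0.90, 0.95):
    print(f"  power {power:.0%}: N = "
          f"{auc_sample_size(power=power, prevalence=0.70)}")
# N grows with the requested power and shrinks as the alternative AUC moves
# away from 0.5.
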