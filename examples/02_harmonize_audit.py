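"""Harmonize an outcome against the packaged instrument table and show the audit.

The outcome here is a synthetic stroke-like dataset that omits one variant
(rs2853953), mimicking a variant unavailable in the outcome GWAS: it is
dropped with an audit record rather than imputed.
"""
import mrkit
from mrkit.simulate import paper_like_study

study = paper_like_study(seed=0, theta=0.0)
h = mrkit.harmonize(study.exposure, study.outcome)

print(f"exposure instruments : {len(study.exposure)}")
print(f"retained after align : {h.n_snp}")
print("audit trail:")
for rec in h.actions:
    print(f"  {rec.rsid:12s} {rec.action:16s} {rec.reason}")

# Every exposure variant appears exactly once: 11 kept unchanged (the
# simulated outcome reports the same effect alleles) and rs2853953 dropped
# as missing from the outcome.
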