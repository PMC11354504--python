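"""Integration recipe: reproduce the published LAS estimate from real data.

REQUIRES EXTERNAL DATA (one download; not run by the test suite):

1. Outcome summary statistics for the East Asian stroke GWAS, deposited in
   the GWAS Catalog under accessions GCST90104544-GCST90104548 (any stroke,
   any ischemic, large-artery, small-vessel, cardioembolic):
   https://www.ebi.ac.uk/gwas/downloads/summary-statistics
   Download the harmonised TSV for the large-artery subtype and pass it
   below (the harmonised hm_* column names are recognized automatically).
2. An East Asian LD correlation matrix (signed r) over the 12 packaged
   instruments, e.g. computed with PLINK from a 1000 Genomes EAS panel,
   written as a tab-separated square matrix with rsid headers.  The
   packaged synthetic LD fixture reproduces the clumping pattern but NOT
   the exact correlations, so headline numbers require the real panel.

With those two files this script runs the canonical IVW over the clumped
instruments and prints the odds ratio, to be compared with the published
OR 0.872 (95% CI 0.786-0.967, p = 0.010) and canonical Q = 3.148.
"""
import sys

import mrkit
from mrkit.instruments import ld_clump

if len(sys.argv) != 3:
    sys.exit("usage: python reproduce_headline.py <las_outcome.tsv> <eas_ld.tsv>\n"
             "(see the module docstring for the external data required)")

outcome_path, ld_path = sys.argv[1], sys.argv[2]
exposure = mrkit.load_chb_instruments()
outcome = mrkit.read_outcome_summary(outcome_path, rsid_filter={v.rsid for v in exposure},
                                     label="LAS")
ld = mrkit.read_ld_matrix(ld_path)

h = mrkit.harmonize(exposure, outcome)
kept = ld_clump([v for v in exposure if v.rsid in set(h.rsids)], ld)
est = mrkit.ivw(h.subset(kept))
q, df, qp = mrkit.cochran_q(h.subset(kept))
print(f"canonical IVW over {est.n_snp} instruments:")
print(f"  OR {est.or_value:.3f} [{est.ci_low:.3f}, {est.ci_high:.3f}]  p={est.pvalue:.3g}")
print(f"  Cochran Q = {q:.3f} (df={df}, p={qp:.3f})")
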