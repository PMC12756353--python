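"""Recompute the concordance statistics of the reference validation cohort.

Loads the bundled observed counts of the 94-patient comparison against the
Lenke classification (curve types vs vertical-index categories, and
sagittal modifiers vs kyphosis-lordosis categories), then recomputes the
Pearson chi-square test of independence and the overall percentage
agreement from those counts.
"""

from scolioclass import load_reference_concordance, pearson_chi_square, percent_agreement

for axis, title in (("vertical", "Lenke type vs vertical index"),
                    ("sagittal", "sagittal modifier vs kl index")):
    table = load_reference_concordance(axis)
    res = pearson_chi_square(table)
    print(f"{title}")
    for g, v, n in zip(table.rows, table.validated, table.not_validated):
        print(f"  {g:>6}: {v:3d} validated / {n:3d} not")
    print(f"  chi2 = {res.statistic:.2f}, df = {res.df}, p = {res.p_value:.2e}")
    print(f"  overall agreement = {percent_agreement(table):.2f}%\n")
# A significant chi-square means validation status is not independent of the
# Lenke group; the agreement percentage is the share of concordant patients.
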