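"""The statistical toolbox: exact Fisher, chi-square, error propagation.

Runs each statistic on small worked inputs and prints the results with the
convention used (two-tailed point-probability Fisher, plain Pearson
chi-square, quotient error propagation in quadrature).
"""

from csrseq.stats import (
    RatioWithSD,
    chi2_test,
    fisher_exact_2x2,
    ratio_with_propagated_sd,
)

# translocation-assay-shaped table: 7 events in 188 assays in both groups
res = fisher_exact_2x2([[7, 181], [7, 181]])
print(f"Fisher [[7,181],[7,181]]: p = {res.p_value}  (identical rows -> 1)")

res = fisher_exact_2x2([[0, 10], [10, 0]])
print(f"Fisher [[0,10],[10,0]]: p = {res.p_value:.3e}  "
      f"(= {res.extra['p_exact']} exactly)")

res = chi2_test([[20, 10], [10, 20]])
print(f"chi2 [[20,10],[10,20]]: statistic = {res.statistic:.4f} "
      f"(closed form 20/3), df = {res.df}, p = {res.p_value:.4f}")

# qPCR-style normalization: (2 +/- 0.2) / (1 +/- 0.1)
ratio = ratio_with_propagated_sd(RatioWithSD(2.0, 0.2), RatioWithSD(1.0, 0.1))
print(f"(2 +/- 0.2)/(1 +/- 0.1) = {ratio.value} +/- {ratio.sd:.4f}")
# Relative errors add in quadrature: sd = 2 * sqrt(0.1^2 + 0.1^2) = 0.2828.
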