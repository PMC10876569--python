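"""Annual complexity metrics and decadal percent change for one pixel.

Computes the yearly mean chlorophyll, elasticity and fractal dimension
of a 25-year synthetic record under the annual data rules (>=100
observed days for the mean and dimension; >=100 consecutive days for
the elasticity), summarizes them with 95% confidence intervals, and
prints the 2003 -> 2022 percent change of each metric.
"""

import numpy as np

from chlcomplex import (SyntheticSpec, annual_table, generate_series,
                        global_mean_ci, percent_change, window_deviation)

# block-structured gaps (long cloudy spells rather than scattered single
# days) leave unbroken runs >100 days, so annual elasticity is computable
series = generate_series(SyntheticSpec(n_days=9131, gap_fraction=0.2,
                                       gap_block_share=1.0,
                                       gap_block_length=40.0, seed=8))

table = annual_table(series, range(1998, 2023), seed=0)
print(table.to_string(index=False,
                      formatters={"mean_chl": "{:.3f}".format,
                                  "elasticity": "{:.3f}".format,
                                  "fd": "{:.3f}".format}))

for metric in ("mean_chl", "elasticity", "fd"):
    vals = table[metric].to_numpy()
    mean, lo, hi, n = global_mean_ci(vals)
    by_year = table.set_index("year")[metric]
    change = percent_change(by_year.get(2003, np.nan),
                            by_year.get(2022, np.nan))
    print(f"{metric}: mean {mean:.3f} (95% CI {lo:.3f}..{hi:.3f}, n={n}); "
          f"2003->2022 change {change:+.1f}%")

se_el, se_fd, n_el, n_fd = window_deviation(series, seed=2, n_trials=10)
print(f"\nwindow deviation (4000-day windows): "
      f"SE(elasticity)={se_el:.4f} over {n_el} trials, "
      f"SE(fd)={se_fd:.4f} over {n_fd} trials")
# A stationary synthetic record: percent changes hover near zero and the
# window SEs are small, echoing the stability of the metric definitions.
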