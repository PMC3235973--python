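"""Wilson score intervals at the small sample sizes of a validation study.

Prints the Wilson 95% CI for a few confirmed/adjudicated counts. Unlike
the Wald interval, the score interval stays inside [0, 100] and gives a
sensible lower bound even when every case confirms (x = n), which is why
validation studies with n in the tens report it.
"""

from dkaval.validation_stats import wilson_interval

for x, n in [(24, 27), (5, 6), (17, 17), (7, 10), (0, 10)]:
    lo, hi = wilson_interval(x, n)
    print(
        f"x={x:2d}, n={n:2d}:  PPV {100 * x / n:5.1f}%   "
        f"95% CI {100 * lo:5.1f} to {100 * hi:5.1f}"
    )
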