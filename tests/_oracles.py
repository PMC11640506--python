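"""Independent oracles shared across test modules."""

import numpy as np
import pandas as pd


def schaefer_index(r, kq, a0, catches, years_start=2014):
    """Propagate Schaefer dynamics forward given a catch series."""
    a = [a0]
    for c in catches:
        a.append(a[-1] + a[-1] * r * (1 - a[-1] / kq) - c)
    return pd.DataFrame(
        {"year": np.arange(years_start, years_start + len(a)), "index": a}
    )


def mann_kendall_bruteforce(x):
    """Exhaustive O(n^2) S statistic."""
    x = np.asarray(x, dtype=float)
    s = 0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            s += int(np.sign(x[j] - x[i]))
    return s
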