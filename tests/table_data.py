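"""Published scenario-1 comparison-table values, used as scoring inputs."""

import numpy as np
import pandas as pd

SCENARIO1_PARAMETRIC = {"h2a": 0.21, "h2d": 0.10, "cor_a": 0.68,
                        "cor_d": 0.48, "vd_va": 0.48}

# method -> (h2a, h2d, cor_a, by_a, cor_d, by_d, vd_va)
SCENARIO1_METHODS = {
    "brr(-2,-2)":      (0.15, 0.12, 0.63, 1.40, 0.31, 0.57, 0.77),
    "iblasso(4,-2)":   (0.12, 0.14, 0.62, 2.41, 0.28, 0.46, 1.19),
    "iblasso(4,2)":    (0.14, 0.10, 0.63, 1.86, 0.29, 0.63, 0.81),
    "bayesa*b*(-2,6)": (0.15, 0.10, 0.63, 1.51, 0.29, 0.69, 0.67),
    "bayesa*b*(4,6)":  (0.15, 0.10, 0.63, 1.49, 0.29, 0.71, 0.65),
    "bayesa*b*(-2,8)": (0.15, 0.09, 0.63, 1.44, 0.29, 0.72, 0.61),
    "rr-het(-2,-2)":   (0.11, 0.14, 0.62, 2.43, 0.28, 0.44, 1.24),
    "blasso(4,2)":     (0.17, 0.13, 0.63, 1.44, 0.29, 3.20, 0.74),
    "g-blup":          (0.15, 0.13, 0.63, 1.25, 0.31, 0.70, 0.83),
    "pedigree":        (0.16, 0.07, 0.53, 0.96, 0.05, 0.20, np.nan),
}

#: published "number of criteria best" column for the same table
SCENARIO1_PRINTED_SCORES = {
    "brr(-2,-2)": 5, "iblasso(4,-2)": 1, "iblasso(4,2)": 4,
    "bayesa*b*(-2,6)": 5, "bayesa*b*(4,6)": 6, "bayesa*b*(-2,8)": 7,
    "rr-het(-2,-2)": 1, "blasso(4,2)": 3, "g-blup": 5, "pedigree": 2,
}


def scenario1_report() -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        SCENARIO1_METHODS, orient="index",
        columns=["h2a", "h2d", "cor_a", "by_a", "cor_d", "by_d", "vd_va"],
    )
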