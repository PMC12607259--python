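"""Reference-cohort summary inputs bundled with the package.

The package is designed around a three-arm cognitive-training trial in
subcortical vascular cognitive impairment (control and training patient
arms, n = 28 each analysed at baseline, plus 26 healthy older adults).
The published baseline demographics and neuropsychological scores are
available only as group-level n / mean / sd summaries and sex counts;
they are shipped here so the summary-statistic entry points of
:mod:`hemilat.stats` can reproduce the trial's baseline test statistics
without access to raw data.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "baseline_summaries",
    "sex_counts",
    "GROUP_SIZES",
]

#: analysed baseline sample sizes per arm
GROUP_SIZES = {"CG": 28, "TG": 28, "HG": 26}

_BASELINE = [
    # measure, CG mean, CG sd, TG mean, TG sd, HG mean, HG sd
    ("age", 65.32, 6.62, 65.68, 8.02, 62.65, 6.11),
    ("education", 10.11, 2.82, 10.61, 3.45, 11.42, 2.87),
    ("moca", 21.25, 3.76, 21.79, 3.88, 26.69, 1.76),
    ("tmt_a", 76.92, 33.50, 83.60, 43.22, 42.51, 12.84),
    ("tmt_b", 151.31, 78.63, 161.21, 86.56, 83.33, 52.35),
    ("tmt_b_a", 74.40, 64.99, 77.61, 56.86, 40.82, 46.75),
    ("avlt_immediate", 19.54, 6.64, 22.79, 6.01, 29.12, 4.76),
    ("avlt_delayed", 6.50, 3.16, 7.29, 2.77, 11.12, 2.72),
    ("avlt_recognition", 10.07, 2.84, 11.07, 2.75, 13.12, 1.84),
    ("digit_span_forward", 7.18, 1.12, 7.25, 1.53, 8.46, 0.86),
    ("digit_span_backward", 4.25, 1.01, 4.25, 1.51, 5.23, 1.48),
    ("bnt", 23.61, 3.52, 22.00, 3.83, 24.85, 5.56),
]

#: female / male counts per arm
_SEX = {"CG": (8, 20), "TG": (12, 16), "HG": (19, 7)}


def baseline_summaries() -> pd.DataFrame:
    """Long-format n/mean/sd baseline summaries, one row per measure x arm."""
    rows = []
    for measure, cg_m, cg_s, tg_m, tg_s, hg_m, hg_s in _BASELINE:
        for group, m, s in (("CG", cg_m, cg_s), ("TG", tg_m, tg_s), ("HG", hg_m, hg_s)):
            rows.append(
                {
                    "measure": measure,
                    "group": group,
                    "n": GROUP_SIZES[group],
                    "mean": m,
                    "sd": s,
                }
            )
    return pd.DataFrame(rows)


def sex_counts(groups: tuple[str, ...] = ("CG", "TG", "HG")) -> pd.DataFrame:
    """Female/male contingency counts for the requested arms."""
    return pd.DataFrame(
        [{"group": g, "female": _SEX[g][0], "male": _SEX[g][1]} for g in groups]
    ).set_index("group")
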