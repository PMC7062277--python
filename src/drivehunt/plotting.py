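"""Plotting conveniences: forest plot of model coefficients, survival
curves, and the day/night displacement profile."""
from __future__ import annotations

import numpy as np

from .models import FitResult
from .returns import SurvivalCurve


def forest_plot(result: FitResult, ax=None, drop_intercept: bool = True):
    """Coefficient estimates with 95% (thin) and 75% (thick) intervals."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    tab = result.table
    if drop_intercept:
        tab = tab[tab["term"] != "intercept"]
    ypos = np.arange(len(tab))[::-1]
    ax.hlines(ypos, tab["l95"], tab["u95"], color="k", lw=1)
    ax.hlines(ypos, tab["l75"], tab["u75"], color="k", lw=3)
    ax.plot(tab["estimate"], ypos, "ko")
    ax.axvline(0, color="grey", ls=":")
    ax.set_yticks(ypos)
    ax.set_yticklabels(tab["term"])
    ax.set_xlabel("coefficient")
    return ax


def km_plot(curves: dict[str, SurvivalCurve], ax=None):
    """Step plot of Kaplan-Meier survival (probability of not having
    returned) with 95% bands, one line per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    for label, c in curves.items():
        ax.step(c.times, c.survival, where="post", label=label)
        ax.fill_between(c.times, c.ci_lower, c.ci_upper, step="post", alpha=0.2)
    ax.set_xlabel("hours since leaving the hunted area")
    ax.set_ylabel("P(not yet returned)")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def displacement_profile_plot(profile, ax=None):
    """Median net displacement per half-day period, one line per response
    group (input from :func:`drivehunt.metrics.displacement_profile`)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.2))
    order = {"day": 0.0, "night": 0.5}
    for group, sub in profile.groupby("group"):
        xs = sub["day_offset"] + sub["period"].map(order)
        srt = np.argsort(xs.to_numpy())
        ax.errorbar(
            xs.to_numpy()[srt],
            sub["median_m"].to_numpy()[srt],
            yerr=np.vstack(
                [
                    (sub["median_m"] - sub["q1_m"]).to_numpy()[srt],
                    (sub["q3_m"] - sub["median_m"]).to_numpy()[srt],
                ]
            ),
            marker="o",
            capsize=2,
            label=group,
        )
    ax.axvline(0, color="r", ls="--", lw=1)
    ax.set_xlabel("days from hunt (day/night half-periods)")
    ax.set_ylabel("median net displacement (m)")
    ax.legend()
    return ax
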