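"""Ethograms, defensive-epoch windows, and group statistics.

An ethogram is the per-frame movement label stream of one trial (the 12
named movements plus flight and freezing — 14 categories), represented as
maximal same-label bouts over half-open intervals.  Trials are windowed into
three defensive epochs relative to stimulus onset: *pre* (the 60 s before
the stimulus), *escape* (stimulus to refuge entry) and *refuge* (refuge
entry to refuge exit).  Per window the module computes category fractions
(time share) and frequencies (bout counts, plus per-minute rates), bout
transition matrices, the Freezing/Non-Freezing group assignment, and the
two-way sex x movement ANOVA with Holm-Sidak (or Tukey) post-hoc contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ALL_CATEGORIES
from .errors import DesignError, WindowError


@dataclass
class Bout:
    """A maximal same-label interval, half-open in seconds."""

    label: str
    start_s: float
    end_s: float

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Ethogram:
    """Per-frame movement labels of one trial, with derived bouts."""

    labels: np.ndarray  # per-frame label (str)
    frame_rate: float
    trial_id: str = ""
    sex: str = "unspecified"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 1 or len(self.labels) == 0:
            raise ValueError("labels must be a non-empty 1D array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def bouts(self) -> list[Bout]:
        """Run-length encode the label stream into maximal bouts."""
        dt = 1.0 / self.frame_rate
        out: list[Bout] = []
        start = 0
        for i in range(1, self.n_frames + 1):
            if i == self.n_frames or self.labels[i] != self.labels[start]:
                out.append(Bout(str(self.labels[start]), start * dt, i * dt))
                start = i
        return out

    def with_defensive(
        self,
        flight: tuple[float, float] | None,
        freezing: list[tuple[float, float]],
    ) -> "Ethogram":
        """Overlay detected flight/freezing intervals onto the label stream."""
        labels = self.labels.copy()
        n = self.n_frames
        for (s, e), name in [(b, "freezing") for b in freezing] + (
            [(flight, "flight")] if flight is not None else []
        ):
            i0 = max(int(round(s * self.frame_rate)), 0)
            i1 = min(int(round(e * self.frame_rate)), n)
            labels[i0:i1] = name
        return Ethogram(labels, self.frame_rate, self.trial_id, self.sex)


@dataclass
class EpochWindows:
    """The three defensive epochs, absolute trial times in seconds."""

    pre: tuple[float, float] | None
    escape: tuple[float, float] | None
    refuge: tuple[float, float] | None

    @classmethod
    def from_events(
        cls,
        stimulus_onset: float,
        refuge_entry: float | None,
        refuge_exit: float | None,
        pre_s: float = 60.0,
    ) -> "EpochWindows":
        pre = (max(stimulus_onset - pre_s, 0.0), stimulus_onset)
        escape = (stimulus_onset, refuge_entry) if refuge_entry is not None else None
        refuge = (
            (refuge_entry, refuge_exit)
            if refuge_entry is not None and refuge_exit is not None
            else None
        )
        return cls(pre=pre, escape=escape, refuge=refuge)


@dataclass
class WindowedEthogram:
    """Bouts clipped to one epoch window."""

    window: tuple[float, float]
    bouts: list[Bout]

    @property
    def duration(self) -> float:
        return self.window[1] - self.window[0]


def window_ethogram(
    etho: Ethogram, windows: EpochWindows, require: tuple[str, ...] = ()
) -> dict[str, WindowedEthogram]:
    """Clip an ethogram's bouts to each defined epoch window.

    Undefined windows (missing refuge events) are omitted from the result;
    naming them in ``require`` raises :class:`WindowError` instead.  Clipped
    bout durations sum to the window length (up to the trial's own end).
    """
    out: dict[str, WindowedEthogram] = {}
    bouts = etho.bouts()
    for name in ("pre", "escape", "refuge"):
        win = getattr(windows, name)
        if win is None:
            if name in require:
                raise WindowError(f"epoch window {name!r} undefined (event missing)")
            continue
        a, b = win
        if b <= a:
            raise WindowError(f"window {name!r} has non-positive length [{a}, {b})")
        clipped = [
            Bout(bt.label, max(bt.start_s, a), min(bt.end_s, b))
            for bt in bouts
            if bt.end_s > a and bt.start_s < b
        ]
        out[name] = WindowedEthogram(window=(a, b), bouts=clipped)
    return out


def require_window(sub: dict[str, WindowedEthogram], name: str) -> WindowedEthogram:
    if name not in sub:
        raise WindowError(f"epoch window {name!r} undefined for this trial (event missing)")
    return sub[name]


def fractions(sub: WindowedEthogram, categories=ALL_CATEGORIES) -> pd.Series:
    """Time share of each category within the window; sums to 1.

    Residual window time not covered by any bout (possible when the trial
    ends inside the window) is reported under ``"unlabeled"``.
    """
    if sub.duration <= 0:
        raise ValueError("zero-length window")
    totals = {c: 0.0 for c in categories}
    covered = 0.0
    for bt in sub.bouts:
        totals[bt.label] = totals.get(bt.label, 0.0) + bt.duration
        covered += bt.duration
    residual = sub.duration - covered
    if residual > 1e-9:
        totals["unlabeled"] = residual
    return pd.Series(totals, dtype=float) / sub.duration


def frequencies(sub: WindowedEthogram, categories=ALL_CATEGORIES) -> pd.DataFrame:
    """Bout counts per category within the window, plus per-minute rates.

    A bout clipped at the window edge counts once.
    """
    if sub.duration <= 0:
        raise ValueError("zero-length window")
    counts = {c: 0 for c in categories}
    for bt in sub.bouts:
        counts[bt.label] = counts.get(bt.label, 0) + 1
    df = pd.DataFrame({"count": pd.Series(counts, dtype=int)})
    df["per_min"] = df["count"] * 60.0 / sub.duration
    return df


def transition_matrix(etho: Ethogram, categories=None) -> pd.DataFrame:
    """Row-stochastic bout-to-bout transition matrix P(next | current).

    Self-transitions are impossible by bout construction, so the diagonal is
    zero; rows without outgoing transitions are all-zero.
    """
    bouts = etho.bouts()
    if len(bouts) < 2:
        raise ValueError("need at least 2 bouts for a transition matrix")
    seq = [b.label for b in bouts]
    cats = list(categories) if categories is not None else sorted(set(seq))
    T = pd.DataFrame(0.0, index=cats, columns=cats)
    for a, b in zip(seq[:-1], seq[1:]):
        T.loc[a, b] += 1.0
    sums = T.sum(axis=1)
    nz = sums > 0
    T.loc[nz] = T.loc[nz].div(sums[nz], axis=0)
    return T


def classify_freezing_group(etho: Ethogram, stimulus_onset: float) -> str:
    """"Freezing" iff at least one freezing bout starts at/after the stimulus."""
    for bt in etho.bouts():
        if bt.label == "freezing" and bt.start_s >= stimulus_onset:
            return "Freezing"
    return "Non-Freezing"


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """Two-way ANOVA plus per-movement post-hoc contrasts."""

    anova: pd.DataFrame  # factor, F, p
    posthoc: pd.DataFrame  # movement, statistic, p_raw, p_adj, significant
    method: str  # "holm-sidak" | "tukey"
    alpha: float = 0.05

    @property
    def any_significant(self) -> bool:
        return bool(self.posthoc["significant"].any())


def compare_groups(
    frac_table: pd.DataFrame,
    design: pd.DataFrame,
    group_col: str = "sex",
    alpha: float = 0.05,
    posthoc: str = "holm-sidak",
    transform: str | None = None,
) -> GroupComparison:
    """Two-way (group x movement) ANOVA on per-animal category fractions.

    Parameters
    ----------
    frac_table
        Animals x movement-categories fraction table (index = animal_id).
    design
        Table with ``animal_id`` and the grouping column (e.g. ``sex``).
    posthoc
        ``"holm-sidak"``: per-movement two-sample t contrasts with
        Holm-Sidak family-wise adjustment (two-level designs);
        ``"tukey"``: Tukey HSD within each movement (multi-level designs,
        e.g. age), adjusted across movements with Holm-Sidak on the
        per-movement minimum Tukey p.
    transform
        ``"arcsine"`` applies the arcsine-square-root variance-stabilising
        transform to the fractions before testing.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multitest import multipletests

    design = design.set_index("animal_id") if "animal_id" in design.columns else design
    groups = design[group_col]
    levels = groups.unique()
    if len(levels) < 2:
        raise DesignError(f"need >= 2 levels of {group_col!r}, got {list(levels)}")
    counts = groups.value_counts()
    if (counts < 2).any():
        raise DesignError("need >= 2 animals per group")

    values = frac_table.copy()
    if transform == "arcsine":
        values = np.arcsin(np.sqrt(values.clip(0.0, 1.0)))
    long = values.reset_index().melt(
        id_vars=values.index.name or "index", var_name="movement", value_name="fraction"
    )
    long = long.rename(columns={values.index.name or "index": "animal_id"})
    long["group"] = long["animal_id"].map(groups)

    model = smf.ols("fraction ~ C(group) * C(movement)", data=long).fit()
    anova = sm.stats.anova_lm(model, typ=2).reset_index().rename(
        columns={"index": "factor", "F": "F", "PR(>F)": "p"}
    )

    from scipy import stats as sps

    rows = []
    for movement in values.columns:
        sub = long[long["movement"] == movement]
        if posthoc == "holm-sidak":
            if len(levels) != 2:
                raise DesignError("holm-sidak post hoc expects a two-level design")
            a = sub.loc[sub["group"] == levels[0], "fraction"]
            b = sub.loc[sub["group"] == levels[1], "fraction"]
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.ttest_ind(a, b, equal_var=True)
        elif posthoc == "tukey":
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            res = pairwise_tukeyhsd(sub["fraction"], sub["group"], alpha=alpha)
            p = float(np.min(res.pvalues)) if len(res.pvalues) else 1.0
            stat = float(np.max(np.abs(res.meandiffs))) if len(res.meandiffs) else 0.0
        else:
            raise ValueError(f"unknown posthoc {posthoc!r}")
        rows.append({"movement": movement, "statistic": float(stat), "p_raw": float(p)})
    ph = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(ph["p_raw"], alpha=alpha, method="holm-sidak")
    ph["p_adj"] = np.maximum(p_adj, ph["p_raw"])  # adjusted p is never below raw
    ph["significant"] = reject
    return GroupComparison(anova=anova, posthoc=ph, method=posthoc, alpha=alpha)


def fraction_table(
    per_animal_fracs: dict[str, pd.Series],
) -> pd.DataFrame:
    """Stack per-animal fraction Series into an animals x categories table."""
    df = pd.DataFrame(per_animal_fracs).T.fillna(0.0)
    df.index.name = "animal_id"
    return df
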