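"""Derived statistics, thresholds and rule-based rod/common TSS classification.

The derived statistics per TSS are:

* ``k4_ratio``   — H3K4me2 PN15/PN1 (pseudocounted): developmental
  accumulation of the active mark.  Rod TSS cluster near 10, common near 2.6.
* ``k4_rd1_depleted`` — H3K4me2 at RD1 (rod-less retina) below PN15: the
  signal is lost when rods degenerate.
* ``delta_polii`` — PolII PN25 − PN2, partitioned at 0 and at a high
  threshold (mean + 2 SD of the positive deltas; 182 on the original data).
* ``dhs_ratio``  — DHS 8W/1D (pseudocounted), partitioned at 1 and at a
  strong threshold (mean + 2 SD of the ratios; 1.35 on the original data).
* ``crx_bound`` / ``nrl_bound`` — transcription-factor binding calls.
  Binding is bimodal: 0 reads means unbound, anything positive bound.

The rule-based signature requires the marks that define the rod cluster:
H3K4me2 developmental accumulation (ratio >= gate), RD1 depletion, and a
developmental DHS increase.  CRX/NRL binding and PolII up-regulation
support the call (a sizeable minority of genuine rod TSS lack them) and
feed a confidence score instead of being required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin

from .features import FeatureMatrix
from .intervals import ValidationError

#: thresholds derived from the original retina data, usable as presets
PAPER_T_POLII = 182.0
PAPER_T_DHS_STRONG = 1.35

STAT_COLUMNS = [
    "k4_ratio", "k4_rd1_depleted", "delta_polii", "dhs_ratio",
    "crx_reads", "nrl_reads", "crx_bound", "nrl_bound",
    "polii_group", "dhs_group",
]


@dataclass
class Thresholds:
    """Classification thresholds; None means derive from the data at fit."""

    t_polii: float | None = None
    t_dhs_strong: float | None = None
    t_dhs_up: float = 1.0
    k4_ratio_min: float = 3.0
    pseudocount: float = 1.0

    def validate(self) -> None:
        if self.t_polii is not None and self.t_polii <= 0:
            raise ValidationError("t_polii must be positive")
        if self.t_dhs_strong is not None and self.t_dhs_strong <= self.t_dhs_up:
            raise ValidationError("t_dhs_strong must exceed t_dhs_up")


def call_binding(reads) -> bool | np.ndarray:
    """Bimodal binding call: 0 reads = unbound, anything above bound."""
    arr = np.asarray(reads, dtype=float)
    if (arr < 0).any():
        raise ValidationError("read counts must be non-negative")
    out = arr > 0
    return bool(out) if np.isscalar(reads) else out


def mean_plus_2sd(values) -> float:
    """mean + 2 x sample standard deviation (ddof=1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError("need at least 2 values for mean + 2 SD")
    return float(arr.mean() + 2.0 * arr.std(ddof=1))


def dev_ratio(late: float, early: float, pseudocount: float = 1.0) -> float:
    """(late + pseudocount) / (early + pseudocount)."""
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if early + pseudocount == 0:
        raise ValidationError("zero denominator: early term and pseudocount both 0")
    return (late + pseudocount) / (early + pseudocount)


def classify_polii(delta, t_polii: float):
    """Partition developmental PolII change into none / low / high.

    delta <= 0 -> none (no or decreasing binding); 0 < delta <= t -> low;
    delta > t -> high.  The boundary value goes to the lower group.
    """
    if t_polii <= 0:
        raise ValidationError("t_polii must be positive")
    d = np.asarray(delta, dtype=float)
    out = np.where(d <= 0, "none", np.where(d <= t_polii, "low", "high"))
    return str(out) if np.isscalar(delta) else out


def classify_dhs(ratio, t_strong: float, t_up: float = 1.0):
    """Partition the DHS developmental ratio into down / up / strong.

    ratio < t_up -> down; t_up <= ratio <= t_strong -> up;
    ratio > t_strong -> strong.
    """
    if t_strong <= t_up:
        raise ValidationError("t_strong must exceed t_up")
    r = np.asarray(ratio, dtype=float)
    if (r <= 0).any():
        raise ValidationError("DHS ratio must be positive")
    out = np.where(r < t_up, "down", np.where(r <= t_strong, "up", "strong"))
    return str(out) if np.isscalar(ratio) else out


def derive_stats(fm: FeatureMatrix, th: Thresholds) -> pd.DataFrame:
    """Compute the derived statistics table from a feature matrix.

    Ratios and the PolII delta use normalized features (cross-library
    comparisons); binding calls use raw counts — zero is preserved by
    normalization so the bimodal call is insensitive either way.
    """
    th.validate()
    nm, raw = fm.norm, fm.raw
    pc = th.pseudocount
    k4_ratio = (nm["H3K4me2_PN15"] + pc) / (nm["H3K4me2_PN1"] + pc)
    dhs_ratio = (nm["DHS_8W"] + pc) / (nm["DHS_1D"] + pc)
    df = pd.DataFrame(index=nm.index)
    df["k4_ratio"] = k4_ratio
    df["k4_rd1_depleted"] = nm["H3K4me2_RD1"] < nm["H3K4me2_PN15"]
    df["delta_polii"] = nm["PolII_PN25"] - nm["PolII_PN2"]
    df["dhs_ratio"] = dhs_ratio
    df["crx_reads"] = raw["CRX_S1"] + raw["CRX_S2"]
    df["nrl_reads"] = raw["NRL_PN28"]
    df["crx_bound"] = call_binding(df["crx_reads"].to_numpy())
    df["nrl_bound"] = call_binding(df["nrl_reads"].to_numpy())
    return df


class RodSignatureClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based rod/common TSS classifier over the 13-feature matrix.

    ``fit`` derives the two data-dependent thresholds when they are not
    preset: the high-PolII cut as mean + 2 SD of the positive PolII deltas
    and the strong-DHS cut as mean + 2 SD of the DHS ratios.  ``predict``
    labels a TSS ``rod`` iff its H3K4me2 ratio clears the gate, RD1 is
    depleted and DHS is developmentally up (``up`` or ``strong``); CRX/NRL
    binding and PolII up-regulation only raise the confidence score.

    Parameters
    ----------
    k4_ratio_min : float — H3K4me2 PN15/PN1 gate (between the reported
        common mean 2.6 and rod mean 10.1).
    pseudocount : float — added to ratio numerators and denominators.
    t_polii, t_dhs_strong : float or None — preset thresholds; None derives
        them from the fitted data.
    t_dhs_up : float — fixed boundary between DHS down and up.
    """

    def __init__(
        self,
        k4_ratio_min: float = 3.0,
        pseudocount: float = 1.0,
        t_polii: float | None = None,
        t_dhs_strong: float | None = None,
        t_dhs_up: float = 1.0,
    ) -> None:
        self.k4_ratio_min = k4_ratio_min
        self.pseudocount = pseudocount
        self.t_polii = t_polii
        self.t_dhs_strong = t_dhs_strong
        self.t_dhs_up = t_dhs_up

    def _thresholds(self) -> Thresholds:
        return Thresholds(
            t_polii=self.t_polii, t_dhs_strong=self.t_dhs_strong,
            t_dhs_up=self.t_dhs_up, k4_ratio_min=self.k4_ratio_min,
            pseudocount=self.pseudocount,
        )

    def fit(self, X: FeatureMatrix, y=None) -> "RodSignatureClassifier":
        th = self._thresholds()
        stats = derive_stats(X, th)
        if self.t_polii is not None:
            self.t_polii_ = float(self.t_polii)
        else:
            pos = stats.loc[stats["delta_polii"] > 0, "delta_polii"]
            self.t_polii_ = mean_plus_2sd(pos) if len(pos) >= 2 else PAPER_T_POLII
        if self.t_dhs_strong is not None:
            self.t_dhs_strong_ = float(self.t_dhs_strong)
        else:
            self.t_dhs_strong_ = mean_plus_2sd(stats["dhs_ratio"])
        if self.t_dhs_strong_ <= self.t_dhs_up:
            self.t_dhs_strong_ = self.t_dhs_up * 1.001
        self.classes_ = np.array(["common", "rod"])
        return self

    def stats(self, X: FeatureMatrix) -> pd.DataFrame:
        """Derived statistics plus the fitted group assignments."""
        df = derive_stats(X, self._thresholds())
        df["polii_group"] = classify_polii(df["delta_polii"].to_numpy(), self.t_polii_)
        df["dhs_group"] = classify_dhs(
            df["dhs_ratio"].to_numpy(), self.t_dhs_strong_, self.t_dhs_up
        )
        return df

    def predict(self, X: FeatureMatrix) -> np.ndarray:
        stats = self.stats(X)
        return self.predict_from_stats(stats)

    def predict_from_stats(self, stats: pd.DataFrame) -> np.ndarray:
        need = {"k4_ratio", "k4_rd1_depleted", "dhs_group"}
        if not need.issubset(stats.columns):
            raise ValidationError(f"stats table missing {sorted(need - set(stats.columns))}")
        rod = (
            (stats["k4_ratio"] >= self.k4_ratio_min)
            & stats["k4_rd1_depleted"]
            & stats["dhs_group"].isin(["up", "strong"])
        )
        return np.where(rod, "rod", "common")

    def confidence(self, X: FeatureMatrix) -> pd.Series:
        """Fraction of the three supporting marks (CRX, NRL, PolII up) present."""
        stats = self.stats(X)
        support = (
            stats["crx_bound"].astype(int)
            + stats["nrl_bound"].astype(int)
            + (stats["polii_group"] != "none").astype(int)
        )
        return support / 3.0


def classify_rod_signature(stats: pd.DataFrame, th: Thresholds) -> np.ndarray:
    """Functional wrapper: rule-based labels from a complete stats table."""
    clf = RodSignatureClassifier(
        k4_ratio_min=th.k4_ratio_min, pseudocount=th.pseudocount,
        t_polii=th.t_polii if th.t_polii is not None else PAPER_T_POLII,
        t_dhs_strong=(
            th.t_dhs_strong if th.t_dhs_strong is not None else PAPER_T_DHS_STRONG
        ),
        t_dhs_up=th.t_dhs_up,
    )
    clf.t_polii_ = clf.t_polii
    clf.t_dhs_strong_ = clf.t_dhs_strong
    required = {"k4_ratio", "k4_rd1_depleted"} | (
        {"dhs_group"} if "dhs_group" in stats.columns else {"dhs_ratio"}
    )
    missing = required - set(stats.columns)
    if missing:
        raise ValidationError(f"stats table missing {sorted(missing)}")
    if "dhs_group" not in stats.columns:
        stats = stats.copy()
        stats["dhs_group"] = classify_dhs(
            stats["dhs_ratio"].to_numpy(), clf.t_dhs_strong_, clf.t_dhs_up
        )
    return clf.predict_from_stats(stats)


def summarize_groups(labels, of_interest) -> tuple[int, int]:
    """(count, percent) of one category; percent rounded half away from zero."""
    labels = list(labels)
    if not labels:
        raise ValidationError("empty label list")
    count = sum(1 for x in labels if x == of_interest)
    pct = round_half_away(100.0 * count / len(labels))
    return count, pct


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def compare_groups(a, b) -> float:
    """Two-tailed unpaired Student's t-test p-value for two groups.

    Degenerate input (zero pooled variance with equal means) returns 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    p = sps.ttest_ind(a, b, equal_var=True).pvalue
    return 1.0 if np.isnan(p) else float(p)
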