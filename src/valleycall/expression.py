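"""Multiplexed count normalisation and FGF response/direct-target calling.

Implements the nCounter-style normalisation chain (positive-control scale
factors, housekeeping content factors, negative-control background
subtraction), two-condition response classification by fold change plus
Welch t-test on log2 counts, cycloheximide direct/indirect target logic,
timepoint Venn overlaps and the enhancer-associated expression rank test.

Two fold-change threshold presets are shipped: ``figure`` (1.5 / 0.25) and
``methods`` (1.25 / 0.75); both appear in the source analysis and the
discrepancy is documented in the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ProbeClass = Literal["endogenous", "positive", "negative", "housekeeping"]
Call = Literal["up", "down", "unchanged"]
TargetClass = Literal[
    "direct_up", "direct_down", "indirect_up", "indirect_down", "unresponsive"
]

#: fold-change thresholds (up, down) by preset name
THRESHOLD_PRESETS: dict[str, tuple[float, float]] = {
    "figure": (1.5, 0.25),
    "methods": (1.25, 0.75),
}
DEFAULT_PRESET = "figure"
DEFAULT_ALPHA = 0.05


@dataclass
class CountTable:
    """Probes x samples counts with probe classes and sample conditions.

    ``counts`` is a DataFrame (rows = probes, columns = sample ids),
    ``probe_class`` a probe-indexed Series, ``condition`` and ``replicate``
    sample-indexed Series.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    condition: pd.Series
    replicate: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.probe_class.index):
            raise ValueError("probe_class index must match counts rows")
        if not self.counts.columns.equals(self.condition.index):
            raise ValueError("condition index must match counts columns")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    def probes_of(self, cls: ProbeClass) -> pd.Index:
        return self.probe_class.index[self.probe_class == cls]

    def samples_of(self, cond: str) -> pd.Index:
        return self.condition.index[self.condition == cond]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        """TSV layout: columns probe, class, then samples named ``condition:replicate``."""
        df = pd.read_csv(path, sep="\t")
        probe_col, class_col = df.columns[:2]
        counts = df.set_index(probe_col).drop(columns=[class_col])
        probe_class = df.set_index(probe_col)[class_col]
        conds, reps = [], []
        for col in counts.columns:
            if ":" not in col:
                raise ValueError(f"sample column {col!r} is not condition:replicate")
            c, r = col.rsplit(":", 1)
            conds.append(c)
            reps.append(int(r))
        return cls(
            counts.astype(float),
            probe_class,
            pd.Series(conds, index=counts.columns),
            pd.Series(reps, index=counts.columns),
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "probe_class", self.probe_class)
        out.index.name = "probe"
        out.to_csv(path, sep="\t", lineterminator="\n")


def _geomean(frame: pd.DataFrame) -> pd.Series:
    return np.exp(np.log(frame.clip(lower=0.5)).mean(axis=0))


def normalize(
    table: CountTable,
    positive_scaling: bool = True,
    content_normalisation: bool = True,
    background_subtraction: bool = True,
) -> CountTable:
    """nCounter-style normalisation; each step independently toggleable.

    1. per-sample scale = mean of per-sample positive-probe geometric means
       / this sample's positive geometric mean;
    2. content factor likewise from housekeeping probes;
    3. background (per-sample mean + 2 sd of negative probes) subtracted,
       floored at 1.
    """
    for cls in ("positive", "housekeeping", "negative"):
        if len(table.probes_of(cls)) == 0:  # type: ignore[arg-type]
            raise ValueError(f"no probes of class {cls!r}")
    counts = table.counts.astype(float).copy()
    if positive_scaling:
        gm = _geomean(counts.loc[table.probes_of("positive")])
        counts = counts * (gm.mean() / gm)
    if content_normalisation:
        gm = _geomean(counts.loc[table.probes_of("housekeeping")])
        counts = counts * (gm.mean() / gm)
    if background_subtraction:
        neg = counts.loc[table.probes_of("negative")]
        bg = neg.mean(axis=0) + 2 * neg.std(axis=0, ddof=1)
        counts = (counts - bg).clip(lower=1.0)
    return CountTable(counts, table.probe_class, table.condition, table.replicate)


@dataclass
class ResponseTable:
    """Per-probe fold change, p-value and up/down/unchanged call for one contrast."""

    table: pd.DataFrame  # columns: fold_change, p_value, call
    treated: str
    control: str
    up_threshold: float
    down_threshold: float
    alpha: float

    @property
    def up(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "up"])

    @property
    def down(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "down"])


def respond(
    table: CountTable,
    treated: str,
    control: str,
    preset: str = DEFAULT_PRESET,
    up: float | None = None,
    down: float | None = None,
    alpha: float = DEFAULT_ALPHA,
    use_fc_thresholds: bool = True,
) -> ResponseTable:
    """Fold change + Welch t-test response calls on endogenous probes.

    Fold change is the linear treated/control ratio of mean normalised
    counts; the p-value is a two-sided unpaired (pooled-variance) t-test on
    log2 counts — at the small replicate numbers this assay uses, the
    Welch degrees-of-freedom correction is markedly conservative.  Calls:
    up iff FC >= up threshold and p <= alpha (thresholds inclusive), down
    iff FC <= down threshold and p <= alpha.  ``use_fc_thresholds=False``
    makes the call purely p-value + direction based.
    """
    if up is None or down is None:
        try:
            preset_up, preset_down = THRESHOLD_PRESETS[preset]
        except KeyError:
            raise ValueError(f"unknown preset {preset!r}") from None
        up = preset_up if up is None else up
        down = preset_down if down is None else down
    t_cols = table.samples_of(treated)
    c_cols = table.samples_of(control)
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("both conditions need >= 2 replicates")
    probes = table.probes_of("endogenous")
    x = table.counts.loc[probes, t_cols].values
    y = table.counts.loc[probes, c_cols].values
    fc = x.mean(axis=1) / y.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance groups give nan, handled below
        _, pvals = stats.ttest_ind(
            np.log2(np.maximum(x, 1.0)),
            np.log2(np.maximum(y, 1.0)),
            axis=1,
            equal_var=True,
        )
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    calls = np.full(len(probes), "unchanged", dtype=object)
    sig = pvals <= alpha
    if use_fc_thresholds:
        calls[sig & (fc >= up)] = "up"
        calls[sig & (fc <= down)] = "down"
    else:
        calls[sig & (fc > 1)] = "up"
        calls[sig & (fc < 1)] = "down"
    df = pd.DataFrame(
        {"fold_change": fc, "p_value": pvals, "call": calls}, index=probes
    )
    return ResponseTable(df, treated, control, up, down, alpha)


@dataclass
class TargetClassification:
    """Direct/indirect FGF-target classes from paired contrasts.

    A probe responding in the same direction both with and without
    translation blocked (cycloheximide) is a direct target; a response
    lost under cycloheximide implies an intermediate protein (indirect).
    Probes called only in the cycloheximide contrast are reported in
    ``chx_only`` and left unclassified.
    """

    classes: pd.Series  # probe -> TargetClass
    chx_only: list[str]

    def of_class(self, cls: TargetClass) -> set[str]:
        return set(self.classes.index[self.classes == cls])


def classify_direct(plain: ResponseTable, chx: ResponseTable) -> TargetClassification:
    if not plain.table.index.equals(chx.table.index):
        raise ValueError("contrasts cover different probe universes")
    out = {}
    chx_only = []
    for probe in plain.table.index:
        p_call = plain.table.at[probe, "call"]
        c_call = chx.table.at[probe, "call"]
        if p_call == "up":
            out[probe] = "direct_up" if c_call == "up" else "indirect_up"
        elif p_call == "down":
            out[probe] = "direct_down" if c_call == "down" else "indirect_down"
        else:
            out[probe] = "unresponsive"
            if c_call != "unchanged":
                chx_only.append(probe)
    return TargetClassification(pd.Series(out), chx_only)


def venn_overlap(r1: ResponseTable, r2: ResponseTable) -> dict[str, int]:
    """Overlap counts of up/down call sets between two contrasts."""
    if not r1.table.index.equals(r2.table.index):
        raise ValueError("contrasts cover different probe universes")
    out = {}
    for direction, s1, s2 in (
        ("up", r1.up, r2.up),
        ("down", r1.down, r2.down),
    ):
        out[f"{direction}_common"] = len(s1 & s2)
        out[f"{direction}_only_1"] = len(s1 - s2)
        out[f"{direction}_only_2"] = len(s2 - s1)
    return out


def enhancer_expression_test(
    expression: Mapping[str, float] | pd.Series,
    with_enhancer: Iterable[str],
) -> dict[str, float]:
    """One-sided Mann-Whitney test: enhancer-associated genes expressed higher?

    Compares the expression of probes with an assigned putative enhancer
    against all remaining probes (alternative: with-enhancer greater).
    Groups smaller than 3 fall back to the exact enumeration with a
    warning; fully tied data yield p = 0.5.
    """
    expr = pd.Series(expression, dtype=float)
    with_set = set(with_enhancer)
    x = expr[expr.index.isin(with_set)].values
    y = expr[~expr.index.isin(with_set)].values
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
        return {
            "p_value": 0.5,
            "median_with": float(np.median(x)),
            "median_without": float(np.median(y)),
        }
    method = "asymptotic"
    if min(len(x), len(y)) < 3:
        warnings.warn("group smaller than 3: using exact enumeration", stacklevel=2)
        method = "exact"
    try:
        res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    except ValueError:  # exact enumeration refuses ties
        res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return {
        "p_value": float(res.pvalue),
        "median_with": float(np.median(x)),
        "median_without": float(np.median(y)),
    }
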