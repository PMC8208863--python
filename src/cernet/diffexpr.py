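"""Differential-expression screening of lncRNAs, miRNAs and mRNAs.

Two-group (case vs. control) screening by Welch's t-test combined with a
linear fold-change gate: a transcript passes when ``p < p_cut`` and
``|signed fold change| > fc_cut``.  The signed fold-change convention
reports the linear case/control mean ratio ``r`` as ``r`` when ``r >= 1``
and as ``-1/r`` when ``r < 1``, so a 4-fold down-regulation prints as
``-4.0`` rather than ``0.25``.

Expression values may be stored on the linear or log2 scale; fold changes
are always computed on the linear scale after back-transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TRANSCRIPT_TYPES = ("lnc", "mi", "m")
SAMPLE_GROUPS = ("case", "control")

#: type label -> conventional name of its passing set
CLASS_LABELS = {"lnc": "DEL", "mi": "DEMi", "m": "DEM"}


@dataclass
class ExpressionMatrix:
    """Transcripts x samples expression with type and group annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by transcript id, columns by sample id.
    transcript_types : pandas.Series
        ``lnc`` / ``mi`` / ``m`` label per transcript id.
    sample_groups : pandas.Series
        ``case`` / ``control`` label per sample id.
    log2 : bool
        Whether ``values`` are on the log2 scale (default) or linear.
    """

    values: pd.DataFrame
    transcript_types: pd.Series
    sample_groups: pd.Series
    log2: bool = True

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate transcript ids: {dupes}")
        self.transcript_types = self.transcript_types.reindex(self.values.index)
        if self.transcript_types.isna().any():
            missing = self.transcript_types.index[self.transcript_types.isna()]
            raise ValueError(f"transcripts without a type label: {list(missing)}")
        bad = set(self.transcript_types) - set(TRANSCRIPT_TYPES)
        if bad:
            raise ValueError(f"unknown transcript types: {sorted(bad)}")
        self.sample_groups = self.sample_groups.reindex(self.values.columns)
        if self.sample_groups.isna().any():
            missing = self.sample_groups.index[self.sample_groups.isna()]
            raise ValueError(f"samples without a group label: {list(missing)}")
        bad = set(self.sample_groups) - set(SAMPLE_GROUPS)
        if bad:
            raise ValueError(f"unknown sample groups: {sorted(bad)}")
        for g in SAMPLE_GROUPS:
            if int((self.sample_groups == g).sum()) < 2:
                raise ValueError(f"need >= 2 samples in group {g!r}")

    # -- accessors ---------------------------------------------------------

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_in(self, group: str) -> list[str]:
        return list(self.sample_groups.index[self.sample_groups == group])

    def rows_of_type(self, ttype: str) -> pd.DataFrame:
        return self.values.loc[self.transcript_types == ttype]

    def row(self, transcript_id: str) -> np.ndarray:
        return self.values.loc[transcript_id].to_numpy(dtype=float)

    def linear_values(self) -> pd.DataFrame:
        """Values on the linear scale (back-transformed if stored as log2)."""
        return np.power(2.0, self.values) if self.log2 else self.values

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, expression_path, groups_path) -> None:
        out = self.values.copy()
        out.insert(0, "type", self.transcript_types.values)
        out.index.name = "transcript_id"
        out.to_csv(expression_path, sep="\t", float_format="%.10g")
        grp = self.sample_groups.rename("group").to_frame()
        grp.index.name = "sample_id"
        grp.to_csv(groups_path, sep="\t")

    @classmethod
    def from_tsv(cls, expression_path, groups_path, log2: bool = True) -> "ExpressionMatrix":
        df = pd.read_csv(expression_path, sep="\t", index_col="transcript_id")
        if "type" not in df.columns:
            raise ValueError("expression table must carry a 'type' column")
        types = df.pop("type")
        grp = pd.read_csv(groups_path, sep="\t", index_col="sample_id")["group"]
        return cls(values=df.astype(float), transcript_types=types,
                   sample_groups=grp, log2=log2)


@dataclass
class DifferentialRecord:
    """Per-transcript screening outcome."""

    transcript_id: str
    transcript_type: str
    fold_change: float
    t_stat: float
    p_value: float
    passes: bool
    bh_q: float = field(default=np.nan)


def t_test_two_group(values_case, values_control, equal_var: bool = False):
    """Two-sided two-sample t-test (Welch by default).

    Returns ``(t_stat, p_value)``.  Degenerate conventions: two identical
    constant groups give ``(0.0, 1.0)``; two different constant groups are
    an infinitely confident separation and give ``p = 0.0`` with a warning.
    """
    a = np.asarray(values_case, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn(
            "both groups constant but unequal; reporting p=0 for a degenerate "
            "zero-variance separation", RuntimeWarning, stacklevel=2)
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def fold_change(values_case, values_control, log2: bool = True) -> float:
    """Signed linear fold change between group means.

    On the log2 scale the means are back-transformed before taking the
    case/control ratio ``r``; the result is ``r`` when ``r >= 1`` and
    ``-1/r`` otherwise.
    """
    a = np.asarray(values_case, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if log2:
        a, b = np.power(2.0, a), np.power(2.0, b)
    mean_case, mean_control = a.mean(), b.mean()
    if mean_case <= 0 or mean_control <= 0:
        raise ValueError("fold change needs positive linear group means")
    r = mean_case / mean_control
    return float(r) if r >= 1.0 else float(-1.0 / r)


def screen(matrix: ExpressionMatrix, p_cut: float = 0.05, fc_cut: float = 2.0,
           equal_var: bool = False) -> pd.DataFrame:
    """Screen every transcript; returns one row per transcript.

    Columns: transcript_id (index), type, fold_change, t, p, bh_q, passes.
    ``passes`` is ``(p < p_cut) and (|fold_change| > fc_cut)`` with strict
    inequalities.  A Benjamini-Hochberg q-value column is reported for
    information; the passing gate uses raw p.
    """
    case = matrix.values[matrix.samples_in("case")].to_numpy(dtype=float)
    ctrl = matrix.values[matrix.samples_in("control")].to_numpy(dtype=float)
    recs = []
    for i, tid in enumerate(matrix.transcript_ids):
        t, p = t_test_two_group(case[i], ctrl[i], equal_var=equal_var)
        fc = fold_change(case[i], ctrl[i], log2=matrix.log2)
        recs.append((tid, matrix.transcript_types.iloc[i], fc, t, p))
    df = pd.DataFrame(recs, columns=["transcript_id", "type", "fold_change", "t", "p"])
    df["bh_q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["passes"] = (df["p"] < p_cut) & (df["fold_change"].abs() > fc_cut)
    return df.set_index("transcript_id")


def partition_by_class(screened: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a screen table into per-class partitions (DELs, DEMis, DEMs)."""
    return {t: screened.loc[screened["type"] == t] for t in TRANSCRIPT_TYPES}


def passing_ids(screened: pd.DataFrame, ttype: str | None = None) -> list[str]:
    """Ids passing the screen, optionally restricted to one transcript class."""
    sel = screened["passes"]
    if ttype is not None:
        sel = sel & (screened["type"] == ttype)
    return list(screened.index[sel])
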