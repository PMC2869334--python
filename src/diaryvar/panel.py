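"""Multi-subject diary panels and the pooled lagged regression design.

A panel holds K subjects observed on an equally spaced daily grid in n
variables, with an explicit missingness mask and optional subject-level
group labels.  Subjects may have different series lengths; the pooled
sample size used by all likelihood computations is N = sum_k (T_k - 1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["PanelTimeSeries", "LaggedDesign", "read_panel", "write_panel", "lagged_design"]


@dataclass
class PanelTimeSeries:
    """K subjects x T occasions x n variables with missingness mask.

    ``values`` is a float array of shape (K, T_max, n); entries beyond a
    subject's own length ``t_lengths[k]`` are padding and always flagged
    unobserved.  A cell is either a finite real or flagged missing, never
    both: missing cells hold NaN and ``observed_mask`` is False there.
    """

    subject_ids: List[str]
    variable_names: List[str]
    values: np.ndarray
    observed_mask: np.ndarray
    group_labels: Optional[Dict[str, str]] = None
    t_lengths: Optional[np.ndarray] = None
    t_starts: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (K, T, n)")
        K, T, n = self.values.shape
        if self.observed_mask is None:
            self.observed_mask = np.isfinite(self.values)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.observed_mask.shape != self.values.shape:
            raise ValueError("observed_mask shape must match values")
        if self.t_lengths is None:
            self.t_lengths = np.full(K, T, dtype=int)
        else:
            self.t_lengths = np.asarray(self.t_lengths, dtype=int)
        if self.t_starts is None:
            self.t_starts = np.ones(K, dtype=int)
        else:
            self.t_starts = np.asarray(self.t_starts, dtype=int)
        self._validate()

    def _validate(self) -> None:
        K, T, n = self.values.shape
        if len(self.subject_ids) != K:
            raise ValueError("subject_ids length must equal K")
        if len(set(self.subject_ids)) != K:
            raise ValueError("subject ids must be unique")
        if len(self.variable_names) != n:
            raise ValueError("variable_names length must equal n")
        if n < 1:
            raise ValueError("need at least one variable")
        if self.t_lengths.min() < 3:
            raise ValueError("every subject needs at least 3 occasions")
        if self.t_lengths.max() > T:
            raise ValueError("t_lengths exceed array extent")
        # observed cells must be finite; missing cells NaN; padding unobserved
        for k in range(K):
            Tk = self.t_lengths[k]
            if self.observed_mask[k, Tk:].any():
                raise ValueError("padding beyond a subject's length must be unobserved")
            obs = self.observed_mask[k, :Tk]
            if not np.isfinite(self.values[k, :Tk][obs]).all():
                raise ValueError(
                    f"non-finite value flagged observed for subject {self.subject_ids[k]}"
                )
        if self.group_labels is not None:
            missing = set(self.subject_ids) - set(self.group_labels)
            if missing:
                raise ValueError(f"group_labels must cover every subject; missing {missing}")

    # ---- basic queries -------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[2]

    @property
    def n_times(self) -> int:
        """Maximum series length across subjects."""
        return self.values.shape[1]

    @property
    def is_fully_observed(self) -> bool:
        return all(
            self.observed_mask[k, : self.t_lengths[k]].all()
            for k in range(self.n_subjects)
        )

    def series(self, k: int, i: int) -> np.ndarray:
        """The (subject k, variable i) series, length T_k, NaN where missing."""
        return self.values[k, : self.t_lengths[k], i]

    def groups(self) -> List[str]:
        if self.group_labels is None:
            return []
        seen: List[str] = []
        for s in self.subject_ids:
            g = self.group_labels[s]
            if g not in seen:
                seen.append(g)
        return seen

    def subset_subjects(self, subjects: Sequence[str]) -> "PanelTimeSeries":
        idx = [self.subject_ids.index(s) for s in subjects]
        labels = None
        if self.group_labels is not None:
            labels = {s: self.group_labels[s] for s in subjects}
        return PanelTimeSeries(
            subject_ids=list(subjects),
            variable_names=list(self.variable_names),
            values=self.values[idx].copy(),
            observed_mask=self.observed_mask[idx].copy(),
            group_labels=labels,
            t_lengths=self.t_lengths[idx].copy(),
            t_starts=self.t_starts[idx].copy(),
        )

    def group_panel(self, group: str) -> "PanelTimeSeries":
        if self.group_labels is None:
            raise ValueError("panel has no group labels")
        subjects = [s for s in self.subject_ids if self.group_labels[s] == group]
        if not subjects:
            raise ValueError(f"no subjects in group {group!r}")
        return self.subset_subjects(subjects)

    def subset_variables(self, names: Sequence[str]) -> "PanelTimeSeries":
        idx = [self.variable_names.index(v) for v in names]
        return PanelTimeSeries(
            subject_ids=list(self.subject_ids),
            variable_names=list(names),
            values=self.values[:, :, idx].copy(),
            observed_mask=self.observed_mask[:, :, idx].copy(),
            group_labels=None if self.group_labels is None else dict(self.group_labels),
            t_lengths=self.t_lengths.copy(),
            t_starts=self.t_starts.copy(),
        )

    def copy_with_values(self, values: np.ndarray, mask: Optional[np.ndarray] = None) -> "PanelTimeSeries":
        return dataclasses.replace(
            self,
            values=np.asarray(values, dtype=float),
            observed_mask=self.observed_mask.copy() if mask is None else mask,
            t_lengths=self.t_lengths.copy(),
            t_starts=self.t_starts.copy(),
        )

    def to_frame(self, missing_sentinel: str = "") -> pd.DataFrame:
        """Long/wide table: one row per subject-occasion."""
        rows = []
        for k, s in enumerate(self.subject_ids):
            Tk = self.t_lengths[k]
            for t in range(Tk):
                row: Dict[str, object] = {"subject": s}
                if self.group_labels is not None:
                    row["group"] = self.group_labels[s]
                row["t"] = int(self.t_starts[k]) + t
                for i, v in enumerate(self.variable_names):
                    row[v] = self.values[k, t, i] if self.observed_mask[k, t, i] else np.nan
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class LaggedDesign:
    """Pooled first-order lagged regression arrays.

    ``predictors[r]`` is the variable vector of some subject at time t-1
    and ``responses[r]`` the same subject's vector at time t.  No pair
    spans two subjects.  ``n_obs`` = sum_k (T_k - 1) is the pooled sample
    size used in all likelihood and information-criterion computations.
    """

    predictors: np.ndarray  # (N, n)
    responses: np.ndarray   # (N, n)
    subject_index: np.ndarray  # (N,) int, index into variable_names order
    variable_names: List[str]

    @property
    def n_obs(self) -> int:
        return self.predictors.shape[0]

    @property
    def n_vars(self) -> int:
        return self.predictors.shape[1]


def lagged_design(panel: PanelTimeSeries) -> LaggedDesign:
    """Build the pooled (t-1, t) pair arrays from a fully observed panel.

    Raises if any cell is missing: imputation must run first.
    """
    if not panel.is_fully_observed:
        raise ValueError(
            "panel has missing cells: run imputation (preprocess.impute_missing) first"
        )
    preds, resps, subj = [], [], []
    for k in range(panel.n_subjects):
        Tk = panel.t_lengths[k]
        x = panel.values[k, :Tk]
        preds.append(x[:-1])
        resps.append(x[1:])
        subj.append(np.full(Tk - 1, k, dtype=int))
    return LaggedDesign(
        predictors=np.concatenate(preds, axis=0),
        responses=np.concatenate(resps, axis=0),
        subject_index=np.concatenate(subj),
        variable_names=list(panel.variable_names),
    )


# ---- delimited-text I/O ---------------------------------------------------


def read_panel(
    path: Union[str, Path],
    subject_col: str = "subject",
    time_col: str = "t",
    group_col: Optional[str] = "group",
    variable_cols: Optional[Sequence[str]] = None,
    delimiter: str = ",",
    missing_sentinel: str = "NA",
) -> PanelTimeSeries:
    """Read a delimited panel file (one row per subject-day, wide format).

    The header must contain the subject column, an integer time column,
    optionally a group column, and at least two numeric variable columns.
    Empty cells or the configured sentinel mean missing.  Time indices
    must be consecutive within each subject; duplicates are rejected.
    """
    df = pd.read_csv(
        path,
        sep=delimiter,
        na_values=[missing_sentinel],
        keep_default_na=True,
        dtype={subject_col: str},
        float_precision="round_trip",
    )
    if subject_col not in df.columns:
        raise ValueError(f"missing subject column {subject_col!r}")
    if time_col not in df.columns:
        raise ValueError(f"missing time column {time_col!r}")
    has_group = group_col is not None and group_col in df.columns
    if variable_cols is None:
        reserved = {subject_col, time_col} | ({group_col} if has_group else set())
        variable_cols = [c for c in df.columns if c not in reserved]
    if len(variable_cols) < 1:
        raise ValueError("no variable columns found")

    subjects = list(dict.fromkeys(df[subject_col]))
    K = len(subjects)
    series_vals: List[np.ndarray] = []
    t_lengths = np.zeros(K, dtype=int)
    t_starts = np.zeros(K, dtype=int)
    group_labels: Optional[Dict[str, str]] = {} if has_group else None
    for k, s in enumerate(subjects):
        sub = df[df[subject_col] == s].sort_values(time_col)
        times = sub[time_col].to_numpy()
        if len(np.unique(times)) != len(times):
            dup = int(times[np.where(np.diff(times) == 0)[0][0]])
            raise ValueError(f"duplicate time index {dup} for subject {s!r}")
        gaps = np.where(np.diff(times) != 1)[0]
        if gaps.size:
            raise ValueError(
                f"non-consecutive time indices for subject {s!r}: gap after t={int(times[gaps[0]])}"
            )
        if len(times) < 3:
            raise ValueError(f"subject {s!r} has fewer than 3 occasions")
        t_lengths[k] = len(times)
        t_starts[k] = int(times[0])
        series_vals.append(sub[list(variable_cols)].to_numpy(dtype=float))
        if has_group:
            glab = sub[group_col].iloc[0]
            group_labels[s] = str(glab)

    T_max = int(t_lengths.max())
    n = len(variable_cols)
    values = np.full((K, T_max, n), np.nan)
    for k in range(K):
        values[k, : t_lengths[k]] = series_vals[k]
    mask = np.isfinite(values)
    return PanelTimeSeries(
        subject_ids=subjects,
        variable_names=list(variable_cols),
        values=values,
        observed_mask=mask,
        group_labels=group_labels,
        t_lengths=t_lengths,
        t_starts=t_starts,
    )


def write_panel(
    panel: PanelTimeSeries,
    path: Union[str, Path],
    delimiter: str = ",",
    missing_sentinel: str = "NA",
    float_format: str = "%.17g",
) -> None:
    """Write a panel as delimited text; round-trips through :func:`read_panel`."""
    cols = ["subject"]
    if panel.group_labels is not None:
        cols.append("group")
    cols += ["t"] + list(panel.variable_names)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(delimiter.join(cols) + "\n")
        for k, s in enumerate(panel.subject_ids):
            Tk = panel.t_lengths[k]
            for t in range(Tk):
                row = [str(s)]
                if panel.group_labels is not None:
                    row.append(str(panel.group_labels[s]))
                row.append(str(int(panel.t_starts[k]) + t))
                for i in range(panel.n_vars):
                    if panel.observed_mask[k, t, i]:
                        row.append(float_format % panel.values[k, t, i])
                    else:
                        row.append(missing_sentinel)
                fh.write(delimiter.join(row) + "\n")
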