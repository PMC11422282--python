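"""Mixed (between-condition x within-time) two-way ANOVA on BOLD timecourses.

The analysis units are (subject x leaf region) pairs -- the structure implied
by the denominator degrees of freedom this design prints (e.g. a composite of
8 leaf areas over 14 subjects gives a condition test on (1, 110) df and an
interaction test on (149, 16390) df with 150 timepoints).  The classical
split-plot decomposition is used: the between-units error (units within
condition) tests the condition effect; the within-units error tests time and
the condition x time interaction.  No sphericity correction is applied by
default (matching the integer df the design reports); a Greenhouse-Geisser
correction is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import LabelAtlas

__all__ = ["TimecourseTable", "AnovaResult", "build_timecourses", "mixed_anova"]


@dataclass
class TimecourseTable:
    """Per-unit mean % BOLD timecourses.

    ``data`` is (n_units, n_volumes); ``condition`` labels each unit;
    ``unit_id`` identifies the (subject, leaf region) pair.
    """

    data: np.ndarray
    condition: np.ndarray
    unit_id: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.condition = np.asarray(self.condition)
        if self.data.ndim != 2:
            raise ValueError("timecourse data must be 2D (units x volumes)")
        if len(self.condition) != self.data.shape[0] or len(self.unit_id) != self.data.shape[0]:
            raise ValueError("condition/unit_id length must match number of units")

    @property
    def n_units(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long format: (unit_id, condition, volume [1-based], value)."""
        n_u, n_t = self.data.shape
        return pd.DataFrame(
            {
                "unit_id": np.repeat(self.unit_id, n_t),
                "condition": np.repeat(self.condition, n_t),
                "volume": np.tile(np.arange(1, n_t + 1), n_u),
                "value": self.data.ravel(),
            }
        )

    def group_mean_se(self) -> pd.DataFrame:
        """Per-condition mean +/- SE per volume (for timecourse figures)."""
        rows = []
        for cond in dict.fromkeys(self.condition.tolist()):
            block = self.data[self.condition == cond]
            rows.append(
                pd.DataFrame(
                    {
                        "condition": cond,
                        "volume": np.arange(1, self.n_volumes + 1),
                        "mean": block.mean(axis=0),
                        "se": block.std(axis=0, ddof=1) / np.sqrt(block.shape[0]),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def build_timecourses(
    pct_by_subject: dict[str, tuple[np.ndarray, np.ndarray]],
    atlas: LabelAtlas,
    composite: str,
    conditions: dict[str, str],
) -> TimecourseTable:
    """Average % BOLD over each leaf region of ``composite`` per subject.

    ``pct_by_subject`` maps subject_id to ``(pct_4d, segmentation_labels)``;
    ``conditions`` maps subject_id to its group.  One unit per (subject,
    leaf); a leaf with zero voxels in a subject's segmentation is dropped
    (and the drop reported by the caller's logs via the returned ids).
    """
    leaves = atlas.leaves_of(composite)
    rows, conds, ids = [], [], []
    for sid in sorted(pct_by_subject):
        pct, labels = pct_by_subject[sid]
        for leaf in leaves:
            lid = atlas.label_of(leaf)
            vox = labels == lid
            if not vox.any():
                continue
            rows.append(pct[vox].mean(axis=0))
            conds.append(conditions[sid])
            ids.append(f"{sid}:{leaf}")
    if not rows:
        raise ValueError(f"no units found for composite {composite!r}")
    return TimecourseTable(
        data=np.vstack(rows), condition=np.array(conds), unit_id=ids
    )


@dataclass
class AnovaResult:
    """F tests for condition, time and condition x time, plus all SS."""

    table: pd.DataFrame  # rows: condition, time, interaction
    ss_units: float
    ss_error: float
    ss_total: float

    def f(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])

    def df(self, effect: str) -> tuple[int, int]:
        row = self.table.loc[effect]
        return int(row["df_num"]), int(row["df_den"])

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def to_dict(self) -> dict:
        out = {
            eff: {
                "F": float(r["F"]),
                "df_num": int(r["df_num"]),
                "df_den": int(r["df_den"]),
                "p": float(r["p"]),
                "ss": float(r["ss"]),
            }
            for eff, r in self.table.iterrows()
        }
        out["ss_units_within_condition"] = self.ss_units
        out["ss_error_within"] = self.ss_error
        out["ss_total"] = self.ss_total
        return out


def mixed_anova(
    table: TimecourseTable, gg_correction: bool = False
) -> AnovaResult:
    """Classical mixed-design two-way ANOVA on a balanced timecourse table.

    Sums of squares by the split-plot decomposition::

        SS_total = SS_condition + SS_units(within cond) + SS_time
                   + SS_cond_x_time + SS_error

    df: condition (g-1, N-g); time (T-1, (N-g)(T-1)); interaction
    ((g-1)(T-1), (N-g)(T-1)), with N units in g conditions over T timepoints.
    Unbalanced group sizes are accepted (the df formulas above still hold);
    unequal series lengths are not.  ``gg_correction`` applies
    Greenhouse-Geisser epsilon to the within-unit tests' df when requested.
    """
    y = table.data
    cond_labels = [c for c in dict.fromkeys(table.condition.tolist())]
    g = len(cond_labels)
    if g < 2:
        raise ValueError("need at least 2 conditions")
    n_units, n_t = y.shape
    if n_t < 2:
        raise ValueError("need at least 2 timepoints")
    if not np.all(np.isfinite(y)):
        raise ValueError("timecourse table contains non-finite values")

    grand = y.mean()
    unit_means = y.mean(axis=1)
    time_means = y.mean(axis=0)

    ss_total = float(((y - grand) ** 2).sum())
    ss_cond = 0.0
    ss_units = 0.0
    ss_int = 0.0
    for c in cond_labels:
        sel = table.condition == c
        n_c = int(sel.sum())
        block = y[sel]
        cond_mean = block.mean()
        ss_cond += n_t * n_c * (cond_mean - grand) ** 2
        ss_units += n_t * float(((unit_means[sel] - cond_mean) ** 2).sum())
        cell_means = block.mean(axis=0)  # per (condition, time)
        ss_int += n_c * float(
            ((cell_means - cond_mean - time_means + grand) ** 2).sum()
        )
    ss_time = float(n_units * ((time_means - grand) ** 2).sum())
    ss_error = ss_total - ss_cond - ss_units - ss_time - ss_int

    df_cond = (g - 1, n_units - g)
    df_time = (n_t - 1, (n_units - g) * (n_t - 1))
    df_int = ((g - 1) * (n_t - 1), (n_units - g) * (n_t - 1))

    ms_units = ss_units / df_cond[1]
    ms_error = ss_error / df_time[1]
    eps = 1.0
    if gg_correction:
        eps = _gg_epsilon(y, table.condition, cond_labels)

    rows = {}
    f_cond = (ss_cond / df_cond[0]) / ms_units if ms_units > 0 else np.inf
    rows["condition"] = (ss_cond, *df_cond, f_cond,
                         float(stats.f.sf(f_cond, *df_cond)))
    for name, ss, df in (("time", ss_time, df_time),
                         ("interaction", ss_int, df_int)):
        f = (ss / df[0]) / ms_error if ms_error > 0 else np.inf
        p = float(stats.f.sf(f, df[0] * eps, df[1] * eps))
        rows[name] = (ss, *df, f, p)
    tbl = pd.DataFrame.from_dict(
        rows, orient="index", columns=["ss", "df_num", "df_den", "F", "p"]
    )
    return AnovaResult(
        table=tbl, ss_units=float(ss_units), ss_error=float(ss_error),
        ss_total=ss_total,
    )


def _gg_epsilon(y: np.ndarray, condition: np.ndarray, cond_labels: list) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-condition
    covariance of the repeated measures."""
    n_t = y.shape[1]
    pooled = np.zeros((n_t, n_t))
    dof = 0
    for c in cond_labels:
        block = y[condition == c]
        if block.shape[0] > 1:
            pooled += np.cov(block, rowvar=False) * (block.shape[0] - 1)
            dof += block.shape[0] - 1
    s = pooled / max(dof, 1)
    mean_diag = np.trace(s) / n_t
    mean_all = s.mean()
    num = (n_t * (mean_diag - mean_all)) ** 2
    den = (n_t - 1) * ((s**2).sum() - 2 * n_t * (s.mean(axis=1) ** 2).sum()
                       + n_t**2 * mean_all**2)
    return float(np.clip(num / den if den > 0 else 1.0, 1.0 / (n_t - 1), 1.0))
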