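"""Data model and I/O for multi-cohort expression + survival data.

An :class:`ExpressionCohort` bundles one cohort's expression matrix
(genes x samples, any monotone-equivalent scale: counts, FPKM/TPM, array
intensities), overall-survival outcomes and an identifier.  Expression files
are delimited matrices with gene symbols in the first column and sample ids
in the header; survival tables have columns ``sample_id,time,event``.
Because downstream features are within-sample orderings, no normalisation is
ever applied here — validation only enforces structural invariants.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionCohort",
    "ValidationReport",
    "CohortError",
    "load_cohort",
    "validate_cohort",
    "write_cohort",
    "write_scores",
    "read_scores",
    "setup_run_log",
]

logger = logging.getLogger("tristage")


class CohortError(ValueError):
    """Structural problem with cohort data (empty intersection, bad event
    codes, non-numeric expression...)."""


@dataclass
class ValidationReport:
    n_dropped_samples: int = 0
    n_dropped_genes: int = 0
    messages: list = field(default_factory=list)

    def log(self, msg: str) -> None:
        self.messages.append(msg)
        logger.info("%s", msg)


@dataclass
class ExpressionCohort:
    """One cohort: expression (genes x samples), survival time and event.

    ``time`` is in whatever unit the cohort uses (days, months); units are
    never converted, so evaluation horizons must be expressed in the same
    unit.  ``event`` is 1 for death, 0 for censoring.
    """

    cohort_id: str
    expr: pd.DataFrame  # genes x samples
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame | None = None

    @property
    def genes(self) -> list:
        return list(self.expr.index)

    @property
    def samples(self) -> list:
        return list(self.expr.columns)

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    @property
    def n_events(self) -> int:
        return int(np.sum(self.event))

    def subset_samples(self, sample_ids) -> "ExpressionCohort":
        pos = [self.samples.index(s) for s in sample_ids]
        return ExpressionCohort(
            cohort_id=self.cohort_id,
            expr=self.expr.iloc[:, pos],
            time=self.time[pos],
            event=self.event[pos],
            covariates=None if self.covariates is None else self.covariates.iloc[pos],
        )


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def load_cohort(expr_path, surv_path, cohort_id: str) -> tuple[ExpressionCohort, ValidationReport]:
    """Load and align one cohort from an expression matrix and a survival table.

    Sample order is taken from the survival table, restricted to samples
    also present in the expression header.  Samples with missing or
    non-positive time, or missing event, are dropped and counted.
    """
    report = ValidationReport()
    raw = _read_table(expr_path)
    expr = raw.set_index(raw.columns[0])
    expr.index.name = "gene"
    coerced = expr.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    nonnum = coerced.isna().values & expr.notna().values
    if nonnum.any():
        i, j = np.argwhere(nonnum)[0]
        raise CohortError(
            f"non-numeric expression cell at gene {expr.index[i]!r}, "
            f"sample {expr.columns[j]!r} in {expr_path}"
        )
    expr = coerced

    surv = _read_table(surv_path)
    required = {"sample_id", "time", "event"}
    if not required.issubset(surv.columns):
        raise CohortError(f"survival table must have columns {sorted(required)}")
    surv = surv.copy()
    surv["sample_id"] = surv["sample_id"].astype(str)
    expr.columns = expr.columns.astype(str)

    in_expr = surv["sample_id"].isin(expr.columns)
    surv = surv[in_expr]
    if len(surv) == 0:
        raise CohortError("empty sample intersection between expression and survival files")

    t = pd.to_numeric(surv["time"], errors="coerce")
    e = pd.to_numeric(surv["event"], errors="coerce")
    keep = t.notna() & (t > 0) & e.notna()
    n_drop = int((~keep).sum())
    if n_drop:
        report.n_dropped_samples += n_drop
        report.log(
            f"{cohort_id}: dropped {n_drop} samples with missing/nonpositive "
            "time or missing event"
        )
    surv = surv[keep]
    if len(surv) == 0:
        raise CohortError("no samples left after dropping invalid survival rows")

    sample_order = list(surv["sample_id"])
    cov_cols = [c for c in surv.columns if c not in ("sample_id", "time", "event")]
    cohort = ExpressionCohort(
        cohort_id=cohort_id,
        expr=expr.loc[:, sample_order],
        time=t[keep].to_numpy(dtype=float),
        event=e[keep].to_numpy(),
        covariates=surv.set_index("sample_id")[cov_cols] if cov_cols else None,
    )
    vrep = validate_cohort(cohort)
    report.n_dropped_genes += vrep.n_dropped_genes
    report.messages.extend(vrep.messages)
    return cohort, report


def validate_cohort(cohort: ExpressionCohort) -> ValidationReport:
    """Enforce the cohort invariants in place; return what was done.

    Duplicate gene symbols are collapsed to the row with the highest mean
    expression (the usual probe-collapse convention).  Missing expression
    values are a hard error — the pair indicator is undefined for them and
    imputation would silently change orderings.  An all-censored cohort is
    only warned about: the Cox screen will refuse it later with a clearer
    message.
    """
    report = ValidationReport()
    expr = cohort.expr

    ev = np.asarray(cohort.event)
    if not np.isin(ev, (0, 1)).all():
        raise CohortError(f"{cohort.cohort_id}: event values outside {{0,1}}")
    cohort.event = ev.astype(int)
    t = np.asarray(cohort.time, dtype=float)
    if not (t > 0).all():
        raise CohortError(f"{cohort.cohort_id}: non-positive survival time")
    if len(t) != expr.shape[1]:
        raise CohortError(f"{cohort.cohort_id}: survival/expression length mismatch")

    if expr.columns.duplicated().any():
        raise CohortError(f"{cohort.cohort_id}: duplicate sample ids")
    if expr.isna().values.any():
        raise CohortError(f"{cohort.cohort_id}: missing expression values are not allowed")

    if expr.index.duplicated().any():
        means = expr.mean(axis=1)
        keep_pos = (
            pd.DataFrame({"gene": expr.index, "mean": means.values, "pos": range(len(expr))})
            .sort_values(["gene", "mean"], ascending=[True, False], kind="mergesort")
            .drop_duplicates("gene")
            .sort_values("pos")["pos"]
            .to_numpy()
        )
        n_dup = len(expr) - len(keep_pos)
        cohort.expr = expr.iloc[keep_pos]
        report.n_dropped_genes += n_dup
        report.log(
            f"{cohort.cohort_id}: collapsed {n_dup} duplicate gene rows, "
            "keeping the highest-mean row per symbol"
        )

    if cohort.n_events == 0:
        report.log(f"{cohort.cohort_id}: warning: no events (all samples censored)")
    return report


def write_cohort(cohort: ExpressionCohort, expr_path, surv_path) -> None:
    """Write a cohort back to the two-file format read by :func:`load_cohort`."""
    cohort.expr.to_csv(expr_path, sep="\t", float_format="%.17g")
    surv = pd.DataFrame(
        {"sample_id": cohort.samples, "time": cohort.time, "event": cohort.event}
    )
    if cohort.covariates is not None:
        surv = surv.join(cohort.covariates.reset_index(drop=True))
    surv.to_csv(surv_path, sep="\t", index=False, float_format="%.17g")


def write_scores(scores, sample_ids, path) -> None:
    """Two-column TSV (sample_id, score) in the cohort's sample order."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(sample_ids):
        raise ValueError(
            f"score vector length {len(scores)} != number of samples {len(sample_ids)}"
        )
    pd.DataFrame({"sample_id": list(sample_ids), "score": scores}).to_csv(
        path, sep="\t", index=False
    )


def read_scores(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["score"].to_numpy(), index=df["sample_id"].astype(str), name="score")


def setup_run_log(out_dir, params: dict, seed=None) -> Path:
    """Write a JSON run log with the seed, package versions and all resolved
    parameters; also attach a file handler to the package logger."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    import sklearn
    import sksurv

    meta = {
        "seed": seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "scikit-survival": sksurv.__version__,
        "params": params,
    }
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(meta, indent=2, default=str))
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    return log_path
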