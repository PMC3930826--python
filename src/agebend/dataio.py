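"""Expression dataset container, TSV I/O, design checks, trim/thin variants.

A cross-sectional expression study is a probe-by-sample matrix with one
measurement per subject, each subject annotated with age (years) and sex.
Downstream trend analysis assumes a complete, finite matrix and an age
distribution that is roughly even per decade, so loading validates both and
:func:`check_design` reports whether the study-design inclusion criteria
(>= 25 samples, every decade from 40 onward populated) are met.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "DesignReport",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "check_design",
    "trim_dataset",
    "thin_dataset",
]

SEX_CATEGORIES = ("female", "male")


class DatasetError(ValueError):
    """Raised when a dataset violates its structural contract."""


@dataclass
class ExpressionDataset:
    """Probe x sample expression matrix with per-sample age and sex.

    Parameters
    ----------
    probe_ids : list of str
        Unique probe identifiers (matrix rows).
    sample_ids : list of str
        Unique sample identifiers (matrix columns).
    ages : ndarray of float
        Per-sample age in years, finite and positive.
    sex : ndarray of str
        Per-sample category, ``"female"`` or ``"male"``.
    values : ndarray, shape (n_probes, n_samples)
        Expression values; log2 scale once ``normalized`` is True.
    gene_map : dict, optional
        Partial probe -> gene identifier mapping.
    normalized : bool
        Set by :func:`agebend.preprocess.normalize_glog` (and by the
        simulator, which emits log-scale data directly); re-normalization
        is refused.
    """

    probe_ids: list
    sample_ids: list
    ages: np.ndarray
    sex: np.ndarray
    values: np.ndarray
    gene_map: dict | None = None
    normalized: bool = False

    def __post_init__(self):
        self.probe_ids = list(self.probe_ids)
        self.sample_ids = list(self.sample_ids)
        self.ages = np.asarray(self.ages, dtype=float)
        self.sex = np.asarray(self.sex, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    # -- contract -----------------------------------------------------------
    def validate(self) -> None:
        p, n = len(self.probe_ids), len(self.sample_ids)
        if self.values.shape != (p, n):
            raise DatasetError(
                f"matrix shape {self.values.shape} != ({p} probes, {n} samples)"
            )
        if len(self.ages) != n or len(self.sex) != n:
            raise DatasetError("ages/sex length does not match sample count")
        if len(set(self.probe_ids)) != p:
            dupes = _duplicates(self.probe_ids)
            raise DatasetError(f"duplicate probe ids: {dupes}")
        if len(set(self.sample_ids)) != n:
            dupes = _duplicates(self.sample_ids)
            raise DatasetError(f"duplicate sample ids: {dupes}")
        if not np.all(np.isfinite(self.ages)) or np.any(self.ages <= 0):
            raise DatasetError("ages must be finite and > 0")
        bad_sex = set(self.sex) - set(SEX_CATEGORIES)
        if bad_sex:
            raise DatasetError(f"unrecognized sex categories: {sorted(bad_sex)}")
        if not np.all(np.isfinite(self.values)):
            raise DatasetError("expression matrix contains non-finite values")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, idx) -> "ExpressionDataset":
        """New dataset with the samples at positions ``idx`` (order kept)."""
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            ages=self.ages[idx],
            sex=self.sex[idx],
            values=self.values[:, idx],
        )

    def copy(self) -> "ExpressionDataset":
        return replace(self, values=self.values.copy(), ages=self.ages.copy(),
                       sex=self.sex.copy())


@dataclass
class DesignReport:
    """Study-design summary against the decade-coverage inclusion criteria."""

    n_samples: int
    age_min: float
    age_max: float
    per_decade_counts: dict = field(default_factory=dict)
    meets_criteria: bool = False


def _duplicates(items) -> list:
    seen, dup = set(), []
    for x in items:
        if x in seen and x not in dup:
            dup.append(x)
        seen.add(x)
    return dup


def read_dataset(expr_path, meta_path, gene_map_path=None) -> ExpressionDataset:
    """Load a probe x sample expression TSV plus a sample metadata TSV.

    The expression file carries a header row of sample ids and a first column
    of probe ids (header ``probe_id``); the metadata file has columns
    ``sample``, ``age``, ``sex``. Sample sets must be identical up to order;
    expression columns are reordered to the metadata row order.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample": str})
    missing_cols = {"sample", "age", "sex"} - set(meta.columns)
    if missing_cols:
        raise DatasetError(f"metadata missing columns: {sorted(missing_cols)}")

    expr_samples = [str(c) for c in expr.columns]
    meta_samples = [str(s) for s in meta["sample"]]
    only_meta = sorted(set(meta_samples) - set(expr_samples))
    only_expr = sorted(set(expr_samples) - set(meta_samples))
    if only_meta or only_expr:
        raise DatasetError(
            "sample sets differ between matrix and metadata; "
            f"metadata-only: {only_meta}; matrix-only: {only_expr}"
        )

    ages = np.empty(len(meta), dtype=float)
    sexes = np.empty(len(meta), dtype=object)
    for i, row in enumerate(meta.itertuples(index=False)):
        try:
            ages[i] = float(row.age)
        except (TypeError, ValueError):
            raise DatasetError(f"unparsable age {row.age!r} in metadata row {i + 1}")
        s = str(row.sex).strip().lower()
        if s in ("f", "female"):
            sexes[i] = "female"
        elif s in ("m", "male"):
            sexes[i] = "male"
        else:
            raise DatasetError(f"unparsable sex {row.sex!r} in metadata row {i + 1}")

    expr.columns = expr_samples
    expr = expr[meta_samples]  # realign columns to metadata order
    values = expr.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise DatasetError("expression matrix contains missing values")

    gene_map = None
    if gene_map_path is not None:
        gm = pd.read_csv(gene_map_path, sep="\t", header=None, dtype=str)
        gene_map = dict(zip(gm.iloc[:, 0], gm.iloc[:, 1]))

    return ExpressionDataset(
        probe_ids=[str(p) for p in expr.index],
        sample_ids=meta_samples,
        ages=ages,
        sex=sexes,
        values=values,
        gene_map=gene_map,
    )


def write_dataset(dataset: ExpressionDataset, expr_path, meta_path) -> None:
    """Write the expression matrix and metadata back to the TSV dialect."""
    expr = pd.DataFrame(
        dataset.values, index=pd.Index(dataset.probe_ids, name="probe_id"),
        columns=dataset.sample_ids,
    )
    expr.to_csv(expr_path, sep="\t", float_format="%.17g")
    meta = pd.DataFrame(
        {"sample": dataset.sample_ids, "age": dataset.ages, "sex": dataset.sex}
    )
    meta.to_csv(meta_path, sep="\t", index=False, float_format="%.17g")


def decade_of(age: float) -> int:
    """Decade bin index: ages bin half-open as [10d, 10(d+1))."""
    return int(math.floor(age / 10.0))


def check_design(dataset: ExpressionDataset, min_samples: int = 25,
                 coverage_from: float = 40.0) -> DesignReport:
    """Report whether the dataset meets the cross-sectional inclusion criteria.

    Criteria: at least ``min_samples`` subjects and every decade bin
    intersecting [max(coverage_from, age_min), age_max] populated.
    """
    ages = dataset.ages
    age_min, age_max = float(ages.min()), float(ages.max())
    counts: dict[int, int] = {}
    for a in ages:
        d = decade_of(a)
        counts[d] = counts.get(d, 0) + 1
    lo = max(coverage_from, age_min)
    required = [d for d in range(decade_of(lo), decade_of(age_max) + 1)
                if 10 * (d + 1) > lo and 10 * d <= age_max]
    meets = dataset.n_samples >= min_samples and all(
        counts.get(d, 0) > 0 for d in required
    )
    return DesignReport(
        n_samples=dataset.n_samples,
        age_min=age_min,
        age_max=age_max,
        per_decade_counts={d: counts[d] for d in sorted(counts)},
        meets_criteria=meets,
    )


def trim_dataset(dataset: ExpressionDataset, min_age: float,
                 max_age: float) -> ExpressionDataset:
    """Restrict to samples with min_age <= age <= max_age, order preserved.

    Used for the age-range robustness experiments (e.g. re-running the
    pipeline on 36-106 or 26-87 windows of a 26-106 cohort).
    """
    if not min_age < max_age:
        raise ValueError("min_age must be < max_age")
    keep = np.nonzero((dataset.ages >= min_age) & (dataset.ages <= max_age))[0]
    if len(keep) < 4:
        raise DatasetError(
            f"trim leaves {len(keep)} samples; at least 4 required for a quadratic fit"
        )
    return dataset.subset_samples(keep)


def thin_dataset(dataset: ExpressionDataset, keep: float = 0.5) -> ExpressionDataset:
    """Half-resolution variant: drop every other sample within each decade.

    Samples are sorted by age inside each decade bin (stable, so ties keep
    their original order) and alternate ones retained starting from the first,
    which keeps per-decade counts within one of half the originals. Only
    ``keep=0.5`` is supported.
    """
    if keep != 0.5:
        raise ValueError("only keep=0.5 is supported")
    kept: list[int] = []
    decades = np.array([decade_of(a) for a in dataset.ages])
    for d in np.unique(decades):
        members = np.nonzero(decades == d)[0]
        order = members[np.argsort(dataset.ages[members], kind="stable")]
        kept.extend(order[::2])
    kept.sort()  # restore original relative sample order
    return dataset.subset_samples(kept)
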