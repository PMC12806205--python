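"""Cohort data model and file I/O.

Expression matrices are stored genes x samples (the common orientation of
published TPM tables) as TSV/CSV or MatrixMarket triplets; clinical tables
are CSV with a fixed header.  ``to_log_tpm`` performs the counts -> TPM ->
log(TPM + 1) transform (natural log) that the scoring model expects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ARMS = ("IO", "Chemo", "Combo")
BOR_CODES = ("CR", "PR", "SD", "PD", "NE")
CLINICAL_COLUMNS = [
    "sample_id", "arm", "pfs_months", "pfs_event",
    "os_months", "os_event", "tps_pct", "tmb", "bor",
]
SCALES = ("counts", "tpm", "log_tpm")


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-expression matrix, genes x samples, with a declared scale."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    scale: str = "tpm"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.scale not in SCALES:
            raise CohortError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if vals.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise CohortError(
                f"matrix shape {vals.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise CohortError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CohortError("duplicate sample ids")
        if not np.all(np.isfinite(vals)):
            raise CohortError("expression values must be finite")
        if self.scale in ("counts", "tpm") and np.any(vals < 0):
            raise CohortError(f"negative values are invalid on scale {self.scale!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.sample_ids))

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return replace(self, sample_ids=tuple(sample_ids),
                       values=self.values[:, cols])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return replace(self, gene_ids=tuple(gene_ids),
                       values=self.values[rows, :])


@dataclass(frozen=True)
class ClinicalTable:
    """One row per sample: treatment arm, PFS/OS outcomes, optional markers."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.copy()
        missing = [c for c in CLINICAL_COLUMNS[:6] if c not in df.columns]
        if missing:
            raise CohortError(f"clinical table missing required columns {missing}")
        for c in ("tps_pct", "tmb", "bor"):
            if c not in df.columns:
                df[c] = np.nan
        df = df[CLINICAL_COLUMNS].reset_index(drop=True)
        if df["sample_id"].duplicated().any():
            raise CohortError("duplicate sample ids in clinical table")
        bad_arm = ~df["arm"].isin(ARMS)
        if bad_arm.any():
            raise CohortError(f"unknown arm values: {sorted(df.loc[bad_arm, 'arm'].unique())}")
        for c in ("pfs_months", "os_months"):
            v = pd.to_numeric(df[c], errors="raise").astype(float)
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise CohortError(f"{c} must be finite and non-negative")
            df[c] = v
        for c in ("pfs_event", "os_event"):
            v = pd.to_numeric(df[c], errors="raise").astype(int)
            if not np.isin(v, [0, 1]).all():
                raise CohortError(f"{c} must be 0/1")
            df[c] = v
        known_bor = df["bor"].isna() | df["bor"].isin(BOR_CODES)
        if not known_bor.all():
            raise CohortError(
                f"unknown BOR codes: {sorted(df.loc[~known_bor, 'bor'].unique())}")
        object.__setattr__(self, "df", df)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.df["sample_id"])

    @property
    def n(self) -> int:
        return len(self.df)

    def subset(self, sample_ids) -> "ClinicalTable":
        sub = self.df.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return ClinicalTable(sub)

    def is_ici(self) -> np.ndarray:
        """Indicator for checkpoint-inhibitor exposure (IO or Combo arm)."""
        return (self.df["arm"] != "Chemo").to_numpy()


@dataclass(frozen=True)
class CohortDataset:
    """An aligned expression matrix + clinical table (same samples, same order)."""

    expr: ExpressionMatrix
    clinical: ClinicalTable

    def __post_init__(self):
        if self.expr.sample_ids != self.clinical.sample_ids:
            raise CohortError("expression and clinical samples differ or are misordered")

    @property
    def n(self) -> int:
        return self.expr.n_samples

    def subset(self, sample_ids) -> "CohortDataset":
        return CohortDataset(self.expr.subset_samples(sample_ids),
                             self.clinical.subset(sample_ids))

    def ici_subset(self) -> "CohortDataset":
        ids = [s for s, f in zip(self.clinical.sample_ids, self.clinical.is_ici()) if f]
        return self.subset(ids)

    def chemo_subset(self) -> "CohortDataset":
        ids = [s for s, f in zip(self.clinical.sample_ids, self.clinical.is_ici()) if not f]
        return self.subset(ids)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path, scale_hint: str = "tpm") -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV (gene rows, sample columns)
    or a MatrixMarket ``.mtx`` triplet with sibling ``<stem>.genes.txt`` /
    ``<stem>.samples.txt`` id files.

    Duplicate gene ids are collapsed to the row with the largest mean
    expression (logged); duplicate sample ids are an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        from scipy.io import mmread

        genes = path.parent / (path.stem + ".genes.txt")
        samples = path.parent / (path.stem + ".samples.txt")
        gene_ids = [l.strip() for l in genes.read_text().splitlines() if l.strip()]
        sample_ids = [l.strip() for l in samples.read_text().splitlines() if l.strip()]
        raw = mmread(str(path))
        mat = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw, dtype=float)
        df = pd.DataFrame(mat, index=gene_ids, columns=sample_ids)
    else:
        sep = _sep_for(path)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(header) != len(set(header)):
            dups = sorted({h for h in header if header.count(h) > 1})
            raise CohortError(f"duplicate sample ids: {dups}")
        try:
            df = pd.read_csv(path, sep=sep, index_col=0,
                             float_precision="round_trip")
            df = df.apply(pd.to_numeric, errors="raise")
        except (ValueError, TypeError):
            raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
            for i, (gene, row) in enumerate(raw.iterrows()):
                for j, v in enumerate(row):
                    try:
                        float(v)
                    except (TypeError, ValueError):
                        raise CohortError(
                            f"non-numeric cell at gene row {gene!r} (row {i + 1}), "
                            f"sample column {raw.columns[j]!r}: {v!r}"
                        ) from None
            raise
    if df.columns.duplicated().any():
        dups = sorted(df.columns[df.columns.duplicated()].unique())
        raise CohortError(f"duplicate sample ids: {dups}")
    if df.index.duplicated().any():
        dup_genes = sorted(df.index[df.index.duplicated()].unique())
        log.warning("collapsing %d duplicate gene ids by max mean expression: %s",
                    len(dup_genes), dup_genes[:10])
        df["_rowmean"] = df.mean(axis=1)
        df = (df.sort_values("_rowmean", ascending=False, kind="stable")
                .groupby(level=0, sort=False).head(1)
                .drop(columns="_rowmean"))
        df = df.loc[~df.index.duplicated()]
        df = df.sort_index(kind="stable")
    return ExpressionMatrix(
        gene_ids=tuple(str(g) for g in df.index),
        sample_ids=tuple(str(s) for s in df.columns),
        values=df.to_numpy(dtype=float),
        scale=scale_hint,
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    path = Path(path)
    # %.17g guarantees bit-exact float64 round trips through text
    expr.to_frame().to_csv(path, sep=_sep_for(path), index_label="gene_id",
                           float_format="%.17g")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.df.to_csv(path, index=False)


def to_log_tpm(expr: ExpressionMatrix, gene_lengths=None) -> ExpressionMatrix:
    """Convert counts or TPM to the log(TPM + 1) scale (natural log).

    Counts require ``gene_lengths`` in kilobases (mapping or Series keyed by
    gene id): rates = count / length_kb, scaled so each sample sums to 1e6.
    """
    if expr.scale == "log_tpm":
        raise CohortError("expression is already on the log_tpm scale")
    vals = expr.values
    if expr.scale == "counts":
        if gene_lengths is None:
            raise CohortError("counts input requires gene_lengths (kb)")
        lengths = pd.Series(gene_lengths, dtype=float)
        missing = [g for g in expr.gene_ids if g not in lengths.index]
        if missing:
            raise CohortError(f"missing gene lengths for: {missing}")
        lk = lengths.loc[list(expr.gene_ids)].to_numpy()
        if np.any(lk <= 0):
            raise CohortError("gene lengths must be positive")
        rate = vals / lk[:, None]
        colsum = rate.sum(axis=0)
        if np.any(colsum <= 0):
            raise CohortError("a sample has zero total expression; cannot form TPM")
        vals = rate / colsum[None, :] * 1e6
    return replace(expr, values=np.log1p(vals), scale="log_tpm")


def align_cohort(expr: ExpressionMatrix, clinical: ClinicalTable) -> CohortDataset:
    """Intersect samples and return an aligned cohort; dropped ids are logged."""
    shared = [s for s in expr.sample_ids if s in set(clinical.sample_ids)]
    if not shared:
        raise CohortError("expression and clinical tables share no samples")
    dropped_expr = sorted(set(expr.sample_ids) - set(shared))
    dropped_clin = sorted(set(clinical.sample_ids) - set(shared))
    if dropped_expr:
        log.warning("dropping %d expression-only samples: %s",
                    len(dropped_expr), dropped_expr[:10])
    if dropped_clin:
        log.warning("dropping %d clinical-only samples: %s",
                    len(dropped_clin), dropped_clin[:10])
    return CohortDataset(expr.subset_samples(shared), clinical.subset(shared))


def split_cohort(cohort: CohortDataset, train_fraction: float = 0.7, seed: int = 0):
    """Random train/test partition stratified by arm x PFS-event status.

    Within each stratum the train size is round(fraction * n) (half-up);
    strata with fewer than 2 samples go entirely to train with a warning.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    df = cohort.clinical.df
    strata = df.groupby(["arm", "pfs_event"], sort=True, observed=True).indices
    train_ids: list[str] = []
    test_ids: list[str] = []
    for key in sorted(strata):
        idx = np.array(strata[key])
        ids = df.loc[idx, "sample_id"].to_numpy()
        if ids.size < 2:
            log.warning("stratum %s has %d sample(s); assigning to train", key, ids.size)
            train_ids.extend(ids)
            continue
        n_train = int(np.floor(train_fraction * ids.size + 0.5))
        perm = rng.permutation(ids.size)
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    order = {s: i for i, s in enumerate(cohort.clinical.sample_ids)}
    train_ids.sort(key=order.get)
    test_ids.sort(key=order.get)
    return cohort.subset(train_ids), cohort.subset(test_ids)
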