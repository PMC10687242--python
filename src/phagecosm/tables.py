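"""Count / metadata / density tables: data model, I/O, validation, scaling.

The central observable of a microcosm experiment is an ASV count table
(samples x amplicon sequence variants, integer reads) accompanied by a
sample design frame (microcosm, replicate, day, treatment, invader level)
and a flow-cytometry density series (cells/mL per microcosm per day).
Scaling relative read abundance by total cell density yields absolute
abundances (ASV copies/mL), the currency of the differential-abundance
stage.  Rarefaction (fixed-depth subsampling without replacement) is the
normalisation used before similarity computations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREATMENTS = ("none", "phage", "antibiotic")
INVADER_LEVELS = ("no", "low", "high")

__all__ = [
    "CountTable",
    "SampleFrame",
    "DensitySeries",
    "AbsoluteTable",
    "AlignedDataset",
    "read_count_table",
    "write_count_table",
    "read_sample_frame",
    "write_sample_frame",
    "read_density_series",
    "write_density_series",
    "align",
    "scale_to_absolute",
    "subsample_counts",
]


class TableError(ValueError):
    """Raised on malformed or inconsistent table inputs."""


@dataclass
class CountTable:
    """Samples x ASVs integer read counts plus per-ASV taxonomy.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, index = sample ids, columns = ASV ids.
    taxonomy : pandas.Series
        Semicolon-separated lineage string per ASV id (may be empty strings).
    """

    counts: pd.DataFrame
    taxonomy: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.taxonomy is None:
            self.taxonomy = pd.Series("", index=self.counts.columns, dtype=object)
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise TableError(f"duplicate sample ids: {dup}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].unique().tolist()
            raise TableError(f"duplicate ASV ids: {dup}")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                bad = np.argwhere(~np.isfinite(arr) | (arr != np.floor(arr)))
                s, a = bad[0]
                raise TableError(
                    f"non-integer count at sample {c.index[s]!r}, ASV {c.columns[a]!r}"
                )
            self.counts = c = c.astype(np.int64)
            arr = c.to_numpy()
        if arr.size and arr.min() < 0:
            s, a = np.argwhere(arr < 0)[0]
            raise TableError(
                f"negative count at sample {c.index[s]!r}, ASV {c.columns[a]!r}"
            )
        missing = c.columns.difference(self.taxonomy.index)
        if len(missing):
            raise TableError(f"taxonomy missing for ASVs: {missing.tolist()}")
        self.taxonomy = self.taxonomy.reindex(c.columns).fillna("")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative(self) -> pd.DataFrame:
        """Relative abundances per sample (rows sum to 1)."""
        sums = self.counts.sum(axis=1)
        if (sums == 0).any():
            zero = sums.index[sums == 0].tolist()
            raise TableError(f"zero-read samples: {zero}")
        return self.counts.div(sums, axis=0)

    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.counts.loc[list(sample_ids)].copy(), self.taxonomy.copy())


@dataclass
class SampleFrame:
    """Per-sample design metadata for the 3 x 3 factorial microcosm layout."""

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "microcosm_id", "replicate", "day", "treatment", "invader_level")

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in self.REQUIRED if c not in f.columns]
        if missing:
            raise TableError(f"sample frame missing columns: {missing}")
        if f["sample_id"].duplicated().any():
            raise TableError("duplicate sample_id in sample frame")
        if f.duplicated(subset=["microcosm_id", "day"]).any():
            raise TableError("duplicate (microcosm_id, day) in sample frame")
        bad_t = set(f["treatment"]) - set(TREATMENTS)
        if bad_t:
            raise TableError(f"unknown treatment levels: {sorted(bad_t)}")
        bad_i = set(f["invader_level"]) - set(INVADER_LEVELS)
        if bad_i:
            raise TableError(f"unknown invader levels: {sorted(bad_i)}")
        self.frame = f.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def groups(self) -> pd.DataFrame:
        """Unique (treatment, invader_level) combinations present."""
        return self.frame[["treatment", "invader_level"]].drop_duplicates().reset_index(drop=True)


@dataclass
class DensitySeries:
    """Flow-cytometry total (and optional living) cell density per microcosm-day."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        for c in ("microcosm_id", "day", "total_density"):
            if c not in f.columns:
                raise TableError(f"density series missing column {c!r}")
        if (f["total_density"] < 0).any():
            raise TableError("negative total_density")
        if "living_fraction" in f.columns:
            lf = f["living_fraction"].dropna()
            if ((lf < 0) | (lf > 1)).any():
                raise TableError("living_fraction outside [0, 1]")
        if f.duplicated(subset=["microcosm_id", "day"]).any():
            raise TableError("duplicate (microcosm_id, day) in density series")
        self.frame = f.reset_index(drop=True)

    def lookup(self, microcosm_id, day) -> float:
        f = self.frame
        hit = f[(f["microcosm_id"] == microcosm_id) & (f["day"] == day)]
        if hit.empty:
            raise TableError(f"no density for microcosm {microcosm_id!r} day {day}")
        return float(hit["total_density"].iloc[0])


@dataclass
class AbsoluteTable:
    """Same shape as CountTable but real-valued ASV copies (or cells) per mL."""

    values: pd.DataFrame
    taxonomy: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.taxonomy is None:
            self.taxonomy = pd.Series("", index=self.values.columns, dtype=object)
        if (self.values.to_numpy() < 0).any():
            raise TableError("negative absolute abundance")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# I/O.  TSV layout: rows = ASVs (first column 'asv_id'), columns = samples,
# optional final 'taxonomy' column with semicolon-separated ranks.  BIOM v2.1
# lives in biomio.py.
# ---------------------------------------------------------------------------


def read_count_table(path, format: str = "tsv") -> CountTable:
    """Read a count table from TSV or BIOM v2.1 (HDF5).

    TSV round-trips bit-identically with :func:`write_count_table`.
    """
    if format == "biom":
        from .biomio import read_biom

        return read_biom(path)
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "asv_id":
        raise TableError(f"first column must be 'asv_id', got {df.columns[0]!r}")
    if df["asv_id"].duplicated().any():
        dup = df["asv_id"][df["asv_id"].duplicated()].tolist()
        raise TableError(f"duplicate asv_id rows: {dup}")
    taxonomy = None
    if df.columns[-1] == "taxonomy":
        taxonomy = pd.Series(df["taxonomy"].to_numpy(), index=df["asv_id"].to_numpy())
        df = df.drop(columns=["taxonomy"])
    sample_cols = list(df.columns[1:])
    mat = np.empty((len(sample_cols), len(df)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        for i, cell in enumerate(df[col]):
            try:
                mat[j, i] = int(cell)
            except ValueError:
                raise TableError(
                    f"non-integer count {cell!r} at asv_id {df['asv_id'].iloc[i]!r}, "
                    f"sample column {col!r}"
                ) from None
    counts = pd.DataFrame(mat, index=sample_cols, columns=df["asv_id"].to_numpy())
    return CountTable(counts, taxonomy)


def write_count_table(table: CountTable, path, format: str = "tsv") -> None:
    if format == "biom":
        from .biomio import write_biom

        write_biom(table, path)
        return
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    out = table.counts.T.copy()
    out.insert(0, "asv_id", out.index)
    out["taxonomy"] = table.taxonomy.reindex(out.index).fillna("").to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_sample_frame(path) -> SampleFrame:
    return SampleFrame(pd.read_csv(path, sep="\t"))


def write_sample_frame(samples: SampleFrame, path) -> None:
    samples.frame.to_csv(path, sep="\t", index=False)


def read_density_series(path) -> DensitySeries:
    return DensitySeries(pd.read_csv(path, sep="\t"))


def write_density_series(density: DensitySeries, path) -> None:
    density.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignment, scaling, subsampling
# ---------------------------------------------------------------------------


@dataclass
class AlignedDataset:
    """Inner join of counts, sample metadata and density on sample identity."""

    counts: CountTable
    samples: SampleFrame
    density: DensitySeries
    dropped: dict = field(default_factory=dict)


def align(
    counts: CountTable,
    samples: SampleFrame,
    density: DensitySeries,
    strict: bool = False,
    min_replicates: int = 2,
) -> AlignedDataset:
    """Inner-join the three tables, reporting dropped records.

    Joins counts and metadata on ``sample_id`` and metadata and density on
    ``(microcosm_id, day)``.  ``dropped`` lists ids absent from the
    intersection.  In strict mode an error is raised if any experimental
    group-day retains fewer than ``min_replicates`` replicates.
    """
    meta = samples.frame
    count_ids = set(counts.sample_ids)
    meta_ids = set(meta["sample_id"])
    shared = count_ids & meta_ids
    dens_keys = set(zip(density.frame["microcosm_id"], density.frame["day"]))
    in_density = np.array(
        [(m, d) in dens_keys for m, d in zip(meta["microcosm_id"], meta["day"])]
    )
    keep_rows = meta[meta["sample_id"].isin(shared).to_numpy() & in_density]
    if keep_rows.empty:
        raise TableError("no samples shared between counts, metadata and density")
    kept_ids = list(keep_rows["sample_id"])
    dropped = {
        "counts_only": sorted(count_ids - set(kept_ids)),
        "metadata_only": sorted(meta_ids - set(kept_ids)),
    }
    sub_meta = SampleFrame(keep_rows.copy())
    if strict:
        sizes = keep_rows.groupby(["treatment", "invader_level", "day"]).size()
        starved = sizes[sizes < min_replicates]
        if len(starved):
            raise TableError(
                f"groups below {min_replicates} replicates after alignment:\n{starved}"
            )
    return AlignedDataset(counts.select_samples(kept_ids), sub_meta, density, dropped)


def scale_to_absolute(
    counts: CountTable,
    density: DensitySeries,
    samples: SampleFrame,
) -> AbsoluteTable:
    """Scale relative read abundance by total cell density.

    ``entry(s, a) = counts(s, a) / sum_a counts(s, a) * total_density(s)``,
    so each row of the result sums to the sample's flow-cytometry density.
    Units are ASV copies/mL (no 16S copy-number correction is applied).
    """
    rel = counts.relative()
    meta = samples.frame.set_index("sample_id")
    missing = [s for s in counts.sample_ids if s not in meta.index]
    if missing:
        raise TableError(f"samples without metadata: {missing}")
    dens = np.array(
        [
            density.lookup(meta.loc[s, "microcosm_id"], meta.loc[s, "day"])
            for s in counts.sample_ids
        ]
    )
    values = rel.mul(dens, axis=0)
    return AbsoluteTable(values, counts.taxonomy.copy())


def subsample_counts(
    counts: CountTable,
    depth: int,
    rng: np.random.Generator,
    strict: bool = False,
) -> tuple[CountTable, list[str]]:
    """Rarefy every sample to ``depth`` reads without replacement.

    Each retained sample is replaced by a multivariate-hypergeometric draw of
    ``depth`` reads from its observed counts, so subsampled counts never
    exceed the originals and every row sums to ``depth``.  Samples whose read
    sum is below ``depth`` are excluded (with a warning, or an error in
    strict mode); the exclusion list is returned alongside the table.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    sums = counts.sample_sums
    excluded = list(sums.index[sums < depth])
    if excluded:
        if strict or len(excluded) == len(sums):
            raise TableError(f"samples below depth {depth}: {excluded}")
        warnings.warn(
            f"excluding {len(excluded)} samples below depth {depth}", stacklevel=2
        )
    kept = [s for s in counts.sample_ids if s not in set(excluded)]
    mat = counts.counts.loc[kept].to_numpy()
    out = np.empty_like(mat)
    for i in range(mat.shape[0]):
        if mat[i].sum() == depth:
            out[i] = mat[i]
        else:
            out[i] = rng.multivariate_hypergeometric(mat[i], depth)
    sub = pd.DataFrame(out, index=kept, columns=counts.counts.columns)
    return CountTable(sub, counts.taxonomy.copy()), excluded
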