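"""Minimal BIOM v2.1 (HDF5) reader/writer for ASV count tables.

Implements the subset of the BIOM 2.1 layout the pipeline needs: table shape,
observation/sample ids, CSR+CSC count matrices and a per-observation
taxonomy metadata dataset (stored as one semicolon-joined lineage string per
ASV).  Written files carry the standard ``format-url`` / ``format-version``
attributes; richer metadata structures produced by other tools are ignored
on read.
"""

from __future__ import annotations

import datetime

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

from .tables import CountTable

_FORMAT_URL = "http://biom-format.org"


def write_biom(table: CountTable, path) -> None:
    """Write a CountTable as a BIOM v2.1 HDF5 file (observations = ASVs)."""
    # BIOM orients the matrix observations x samples; our frame is the transpose
    mat = sparse.csr_matrix(table.counts.to_numpy().T)
    csc = mat.tocsc()
    with h5py.File(path, "w") as h5:
        h5.attrs["id"] = "No Table ID"
        h5.attrs["type"] = "OTU table"
        h5.attrs["format-url"] = _FORMAT_URL
        h5.attrs["format-version"] = np.array([2, 1], dtype=np.int64)
        h5.attrs["generated-by"] = "phagecosm"
        h5.attrs["creation-date"] = datetime.datetime.now().isoformat()
        h5.attrs["shape"] = np.array(mat.shape, dtype=np.int64)
        h5.attrs["nnz"] = int(mat.nnz)
        str_dt = h5py.string_dtype(encoding="utf-8")
        obs = h5.create_group("observation")
        obs.create_dataset("ids", data=np.array(table.asv_ids, dtype=object), dtype=str_dt)
        om = obs.create_group("matrix")
        om.create_dataset("data", data=mat.data.astype(np.float64))
        om.create_dataset("indices", data=mat.indices.astype(np.int64))
        om.create_dataset("indptr", data=mat.indptr.astype(np.int64))
        ometa = obs.create_group("metadata")
        ometa.create_dataset(
            "taxonomy",
            data=np.array(table.taxonomy.reindex(table.asv_ids).fillna("").to_numpy(), dtype=object),
            dtype=str_dt,
        )
        obs.create_group("group-metadata")
        smp = h5.create_group("sample")
        smp.create_dataset("ids", data=np.array(table.sample_ids, dtype=object), dtype=str_dt)
        sm = smp.create_group("matrix")
        sm.create_dataset("data", data=csc.data.astype(np.float64))
        sm.create_dataset("indices", data=csc.indices.astype(np.int64))
        sm.create_dataset("indptr", data=csc.indptr.astype(np.int64))
        smp.create_group("metadata")
        smp.create_group("group-metadata")


def read_biom(path) -> CountTable:
    """Read a BIOM v2.1 HDF5 file into a CountTable."""
    with h5py.File(path, "r") as h5:
        n_obs, n_samp = (int(x) for x in h5.attrs["shape"])
        asv_ids = [_s(x) for x in h5["observation/ids"][:]]
        sample_ids = [_s(x) for x in h5["sample/ids"][:]]
        mat = sparse.csr_matrix(
            (
                h5["observation/matrix/data"][:],
                h5["observation/matrix/indices"][:],
                h5["observation/matrix/indptr"][:],
            ),
            shape=(n_obs, n_samp),
        )
        taxonomy = None
        if "observation/metadata" in h5 and "taxonomy" in h5["observation/metadata"]:
            raw = h5["observation/metadata/taxonomy"][:]
            if raw.ndim == 1:
                lineages = [_s(x) for x in raw]
            else:  # rank-split layout used by some writers
                lineages = ["; ".join(_s(r) for r in row if _s(r)) for row in raw]
            taxonomy = pd.Series(lineages, index=asv_ids)
    dense = np.asarray(mat.todense()).T  # samples x ASVs
    counts = pd.DataFrame(np.rint(dense).astype(np.int64), index=sample_ids, columns=asv_ids)
    return CountTable(counts, taxonomy)


def _s(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)
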