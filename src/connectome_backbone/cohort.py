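"""Multi-subject fiber-count cohort: the raw input of the analysis.

A cohort holds, per scan (subject x timepoint), a symmetric nonnegative
integer region-pair fiber-count matrix, an optional matrix of mean fiber
lengths (mm, 0 where no fibers were found), and scan metadata (subject id,
age group, sex).  Matrices are indexed by a :class:`~.atlas.RegionAtlas`.

On-disk layout (all plain text):

* counts: one TSV per scan, N rows x N columns of integers;
* lengths: same shape, floating point millimetres;
* metadata: CSV with columns ``scan_id, subject_id, age_group, sex``;
* atlas: two-column TSV (label, hemisphere).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, read_atlas, write_atlas


@dataclass
class FiberCountCohort:
    counts: np.ndarray        # (n_scans, N, N) nonnegative ints
    lengths: np.ndarray | None  # (n_scans, N, N) mm, 0 where counts == 0
    subjects: pd.DataFrame    # one row per scan
    atlas: RegionAtlas

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        n = self.atlas.n_regions
        if c.ndim != 3 or c.shape[1:] != (n, n):
            raise ValueError(f"counts must be (n_scans, {n}, {n}), got {c.shape}")
        if c.shape[0] != len(self.subjects):
            raise ValueError("one metadata row per scan required")
        if np.any(c < 0):
            raise ValueError("fiber counts must be nonnegative")
        if not np.array_equal(c, np.swapaxes(c, 1, 2)):
            raise ValueError("count matrices must be symmetric")
        if np.any(np.diagonal(c, axis1=1, axis2=2) != 0):
            raise ValueError("count matrices must have zero diagonal")
        if self.lengths is not None:
            ln = np.asarray(self.lengths)
            if ln.shape != c.shape:
                raise ValueError("lengths must match counts in shape")
            if np.any((ln > 0) & (c == 0)):
                raise ValueError("lengths present where counts are zero")
        if "scan_id" not in self.subjects.columns:
            raise ValueError("metadata needs a scan_id column")
        if self.subjects["scan_id"].duplicated().any():
            raise ValueError("scan_id values must be unique")

    @property
    def n_scans(self) -> int:
        return self.counts.shape[0]

    def scan_indices(self, group_by: str, group: str) -> np.ndarray:
        """Row indices of scans whose metadata column ``group_by`` equals ``group``."""
        if group_by not in self.subjects.columns:
            raise KeyError(f"no metadata column {group_by!r}")
        idx = np.flatnonzero((self.subjects[group_by] == group).to_numpy())
        if idx.size == 0:
            raise ValueError(f"no scans with {group_by} == {group!r}")
        return idx

    def groups(self, group_by: str = "age_group") -> list[str]:
        return list(dict.fromkeys(self.subjects[group_by].tolist()))


def _read_square_matrix(path: str | Path, n: int, dtype) -> np.ndarray:
    m = np.atleast_2d(np.loadtxt(path, dtype=dtype, delimiter="\t"))
    if m.shape != (n, n):
        raise ValueError(f"shape mismatch: {path} is {m.shape}, atlas has {n} regions")
    return m


def read_cohort(
    count_files: Mapping[str, str | Path] | Sequence[str | Path],
    atlas_file: str | Path,
    metadata_file: str | Path,
    length_files: Mapping[str, str | Path] | Sequence[str | Path] | None = None,
) -> FiberCountCohort:
    """Assemble a cohort from per-scan count matrices plus atlas and metadata.

    ``count_files`` is either a mapping ``scan_id -> path`` (joined against
    the metadata's ``scan_id`` column) or a sequence parallel to the
    metadata rows.  Matrices must be square (atlas-sized), exactly
    symmetric, with nonnegative integer entries; the diagonal is forced to
    zero.  Asymmetry is an error, not a dialect: it indicates an upstream
    bug and is never silently repaired.
    """
    atlas = read_atlas(atlas_file)
    meta = pd.read_csv(metadata_file, dtype=str)
    if "scan_id" not in meta.columns:
        if meta["subject_id"].duplicated().any():
            raise ValueError("metadata without scan_id must have unique subject_id")
        meta = meta.assign(scan_id=meta["subject_id"])
    scan_ids = meta["scan_id"].tolist()

    def to_list(files, what: str) -> list[Path]:
        if files is None:
            return []
        if isinstance(files, Mapping):
            unknown = sorted(set(files) - set(scan_ids))
            if unknown:
                raise ValueError(f"unknown subject id(s) in {what}: {unknown}")
            missing = sorted(set(scan_ids) - set(files))
            if missing:
                raise ValueError(f"no {what} file for scan(s): {missing}")
            return [Path(files[s]) for s in scan_ids]
        files = list(files)
        if len(files) != len(scan_ids):
            raise ValueError(f"{len(files)} {what} files for {len(scan_ids)} scans")
        return [Path(f) for f in files]

    n = atlas.n_regions
    counts = np.zeros((len(scan_ids), n, n), dtype=np.int64)
    for k, f in enumerate(to_list(count_files, "count")):
        m = _read_square_matrix(f, n, np.int64)
        if not np.array_equal(m, m.T):
            raise ValueError(f"asymmetric count matrix: {f}")
        np.fill_diagonal(m, 0)
        counts[k] = m

    lengths = None
    if length_files is not None:
        lengths = np.zeros((len(scan_ids), n, n), dtype=float)
        for k, f in enumerate(to_list(length_files, "length")):
            m = _read_square_matrix(f, n, float)
            if not np.array_equal(m, m.T):
                raise ValueError(f"asymmetric length matrix: {f}")
            np.fill_diagonal(m, 0.0)
            lengths[k] = m

    return FiberCountCohort(counts=counts, lengths=lengths, subjects=meta, atlas=atlas)


def write_cohort(cohort: FiberCountCohort, out_dir: str | Path) -> dict[str, object]:
    """Write a cohort to ``out_dir`` in the plain-text layout read_cohort_dir expects.

    Returns the file manifest (paths keyed by role).
    """
    out = Path(out_dir)
    (out / "counts").mkdir(parents=True, exist_ok=True)
    if cohort.lengths is not None:
        (out / "lengths").mkdir(exist_ok=True)
    count_files: dict[str, Path] = {}
    length_files: dict[str, Path] = {}
    for k, sid in enumerate(cohort.subjects["scan_id"]):
        p = out / "counts" / f"{sid}.tsv"
        np.savetxt(p, cohort.counts[k], fmt="%d", delimiter="\t")
        count_files[sid] = p
        if cohort.lengths is not None:
            q = out / "lengths" / f"{sid}.tsv"
            np.savetxt(q, cohort.lengths[k], fmt="%.17g", delimiter="\t")
            length_files[sid] = q
    write_atlas(cohort.atlas, out / "atlas.tsv")
    cohort.subjects.to_csv(out / "metadata.csv", index=False)
    return {
        "counts": count_files,
        "lengths": length_files or None,
        "atlas": out / "atlas.tsv",
        "metadata": out / "metadata.csv",
    }


def read_cohort_dir(in_dir: str | Path) -> FiberCountCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    d = Path(in_dir)
    meta = pd.read_csv(d / "metadata.csv", dtype=str)
    ids = meta["scan_id"].tolist()
    counts = {s: d / "counts" / f"{s}.tsv" for s in ids}
    lengths = None
    if (d / "lengths").is_dir():
        lengths = {s: d / "lengths" / f"{s}.tsv" for s in ids}
    return read_cohort(counts, d / "atlas.tsv", d / "metadata.csv", lengths)
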