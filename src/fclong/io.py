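"""Manifests, FC file formats and run provenance.

All tabular outputs are TSV with '#'-prefixed metadata header lines carrying
the seed, a config hash and the edge ordering (row-major strict upper
triangle), so any published number is traceable to one run record.  Floats
are written with 17 significant digits, which round-trips IEEE doubles
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import DataError, FormatError
from .netblocks import ScanPair, SingleScan

log = logging.getLogger(__name__)

EDGE_ORDERING = "row-major-strict-upper-triangle"

MANIFEST_REQUIRED = ("subject_id", "scan1", "scan2")


@dataclass
class CohortManifest:
    """Validated cohort table: one row per subject with scan paths/ids and
    covariates.  Rows with only the second scan are legal for cross-sectional
    use but rejected when a longitudinal analysis is requested."""

    table: pd.DataFrame
    mode: str = "longitudinal"

    @property
    def n_subjects(self) -> int:
        return len(self.table)


def read_manifest(path, mode: str = "longitudinal") -> CohortManifest:
    """Read and validate a cohort manifest CSV.

    Requires ``subject_id`` and ``scan1``/``scan2`` columns (``scan2`` may be
    empty row-wise); optional ``sex``, ``age``, ``age_group`` and phenotype
    columns pass through.  Duplicate subject ids and rows missing required
    fields are errors naming the offending id / row numbers.  Scan paths are
    not opened here; unreadable files surface per subject at load time.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in ("subject_id", "scan1") if c not in df.columns]
    if missing_cols:
        raise FormatError(f"manifest {path} lacks columns {missing_cols}")
    ids = df["subject_id"].astype(str)
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise FormatError(f"duplicate subject id {dup.iloc[0]!r} in manifest")
    has1 = df["scan1"].notna() if "scan1" in df else pd.Series(False, index=df.index)
    has2 = df["scan2"].notna() if "scan2" in df.columns else pd.Series(False, index=df.index)
    if mode == "longitudinal":
        bad = df.index[~(has1 & has2)].tolist()
        if bad:
            raise FormatError(
                f"longitudinal mode requires both scans; rows missing one: "
                f"{[b + 2 for b in bad]} (1-based file lines)"
            )
    else:
        bad = df.index[~(has1 | has2)].tolist()
        if bad:
            raise FormatError(f"rows with no scan at all: {[b + 2 for b in bad]}")
    return CohortManifest(table=df, mode=mode)


@dataclass
class RunRecord:
    """Provenance for one analysis run; embedded in every output."""

    command: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    excluded: dict = field(default_factory=dict)
    version: str = __version__

    @property
    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self.config), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def header_lines(self) -> list[str]:
        lines = [
            f"# fclong_version={self.version}",
            f"# command={self.command}",
            f"# seed={self.seed}",
            f"# config_hash={self.config_hash}",
            f"# edge_ordering={EDGE_ORDERING}",
        ]
        for key, val in sorted(self.excluded.items()):
            lines.append(f"# excluded_{key}={val}")
        return lines

    def to_json(self) -> str:
        payload = _jsonable(asdict(self))
        payload["config_hash"] = self.config_hash
        return json.dumps(payload, indent=2, sort_keys=True, default=str)


def _jsonable(obj):
    """Recursively make mappings JSON-safe (block-key tuples become 'a-b')."""
    if isinstance(obj, dict):
        return {
            "-".join(map(str, k)) if isinstance(k, tuple) else str(k):
                _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_with_header(path: Path, record: RunRecord | None,
                       body: str) -> None:
    header = "\n".join(record.header_lines()) + "\n" if record else ""
    Path(path).write_text(header + body)


def write_fc_vectors(
    path,
    vectors: np.ndarray,
    subject_ids: Sequence[str],
    n_rois: int,
    record: RunRecord | None = None,
) -> None:
    """Stacked FC vectors (one row per scan) as TSV; bit-exact round trip."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim == 1:
        vectors = vectors[None, :]
    lines = ["subject_id\t" + "\t".join(
        f"e{i}" for i in range(vectors.shape[1]))]
    for sid, row in zip(subject_ids, vectors):
        lines.append(sid + "\t" + "\t".join(f"{v:.17g}" for v in row))
    rec = record or RunRecord(command="write-fc")
    rec.config.setdefault("n_rois", n_rois)
    body = f"# n_rois={n_rois}\n" + "\n".join(lines) + "\n"
    _write_with_header(Path(path), rec, body)


def read_fc_vectors(path) -> tuple[np.ndarray, list[str], dict]:
    """Inverse of :func:`write_fc_vectors`: (vectors, subject_ids, metadata)."""
    meta: dict[str, str] = {}
    rows, ids = [], []
    header: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            continue
        ids.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    if header is None:
        raise FormatError(f"{path} holds no table")
    return np.asarray(rows, dtype=float), ids, meta


def write_matrix_tsv(path, matrix: np.ndarray, labels: Sequence | None = None,
                     record: RunRecord | None = None) -> None:
    matrix = np.asarray(matrix, dtype=float)
    labels = list(labels) if labels is not None else list(range(matrix.shape[0]))
    lines = ["\t" + "\t".join(str(l) for l in labels)]
    for lab, row in zip(labels, matrix):
        lines.append(str(lab) + "\t" + "\t".join(f"{v:.17g}" for v in row))
    _write_with_header(Path(path), record, "\n".join(lines) + "\n")


def write_table_tsv(path, table: pd.DataFrame,
                    record: RunRecord | None = None) -> None:
    _write_with_header(Path(path), record,
                       table.to_csv(sep="\t", float_format="%.17g"))


# ---------------------------------------------------------------------------
# cohort directories (what `fclong simulate` writes and the analysis
# subcommands read)


def write_cohort_dir(outdir, cohort, record: RunRecord) -> None:
    """Persist a synthetic cohort: manifest.csv plus stacked FC TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort.pairs is not None:
        rows = [{
            "subject_id": p.subject_id, "scan1": "fc_younger.tsv",
            "scan2": "fc_older.tsv", "sex": p.sex, "age": p.age,
            "age_group": p.age_group, **p.phenotypes,
        } for p in cohort.pairs]
        ids = [p.subject_id for p in cohort.pairs]
        n_rois = cohort.pairs[0].n_rois
        write_fc_vectors(out / "fc_younger.tsv",
                         np.stack([p.younger for p in cohort.pairs]),
                         ids, n_rois, record)
        write_fc_vectors(out / "fc_older.tsv",
                         np.stack([p.older for p in cohort.pairs]),
                         ids, n_rois, record)
    else:
        rows = [{
            "subject_id": s.subject_id, "scan1": "fc.tsv", "scan2": "",
            "sex": s.sex, "age": s.age, "age_group": s.age_group,
        } for s in cohort.scans]
        ids = [s.subject_id for s in cohort.scans]
        n_rois = cohort.scans[0].n_rois
        write_fc_vectors(out / "fc.tsv",
                         np.stack([s.fc for s in cohort.scans]),
                         ids, n_rois, record)
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    (out / "run_record.json").write_text(record.to_json())
    # the atlas the cohort was generated against, for self-contained reruns
    atlas = cohort.config.resolved_atlas()
    atlas_df = pd.DataFrame({
        "roi_id": np.arange(atlas.n_rois),
        "x_mm": atlas.centers_mm[:, 0],
        "y_mm": atlas.centers_mm[:, 1],
        "z_mm": atlas.centers_mm[:, 2],
        "radius_mm": atlas.radii_mm,
        "network_label": atlas.network_labels,
        "network_name": list(atlas.network_names) or [""] * atlas.n_rois,
    })
    atlas_df.to_csv(out / "atlas.tsv", sep="\t", index=False)


def read_cohort_dir(indir) -> tuple[list[ScanPair] | list[SingleScan], "pd.DataFrame"]:
    """Load a cohort directory back into scan pairs or single scans."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    longitudinal = (indir / "fc_younger.tsv").exists()
    if longitudinal:
        younger, ids_y, meta = read_fc_vectors(indir / "fc_younger.tsv")
        older, ids_o, _ = read_fc_vectors(indir / "fc_older.tsv")
        if ids_y != ids_o:
            raise FormatError("younger/older subject orders disagree")
        n_rois = int(meta.get("n_rois", 0)) or _infer_n(younger.shape[1])
        extra = [c for c in manifest.columns
                 if c not in ("subject_id", "scan1", "scan2", "sex", "age",
                              "age_group")]
        by_id = manifest.set_index(manifest["subject_id"].astype(str))
        out: list[ScanPair] = []
        for i, sid in enumerate(ids_y):
            row = by_id.loc[sid]
            out.append(ScanPair(
                subject_id=sid, younger=younger[i], older=older[i],
                n_rois=n_rois, sex=_opt(row.get("sex")),
                age=_optf(row.get("age")), age_group=_opt(row.get("age_group")),
                phenotypes={c: row[c] for c in extra},
            ))
        return out, manifest
    vectors, ids, meta = read_fc_vectors(indir / "fc.tsv")
    n_rois = int(meta.get("n_rois", 0)) or _infer_n(vectors.shape[1])
    by_id = manifest.set_index(manifest["subject_id"].astype(str))
    scans: list[SingleScan] = []
    for i, sid in enumerate(ids):
        row = by_id.loc[sid]
        scans.append(SingleScan(
            subject_id=sid, fc=vectors[i], n_rois=n_rois,
            sex=_opt(row.get("sex")), age=_optf(row.get("age")),
            age_group=_opt(row.get("age_group")),
        ))
    return scans, manifest


def _infer_n(n_edges: int) -> int:
    n = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if n * (n - 1) // 2 != n_edges:
        raise DataError(f"edge count {n_edges} is not of the form N(N-1)/2")
    return n


def _opt(v):
    return None if v is None or (isinstance(v, float) and np.isnan(v)) \
        or (isinstance(v, str) and not v) else str(v)


def _optf(v):
    try:
        f = float(v)
    except (TypeError, ValueError):
        return None
    return None if np.isnan(f) else f
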