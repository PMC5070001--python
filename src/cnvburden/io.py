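"""Readers and writers for the pipeline's external file dialects.

Tabular files are TSV.  Interval coordinates are stored 0-based half-open
(the BED convention); readers accept ``one_based=True`` for 1-based
inclusive inputs and convert at the boundary.  GFF3 (1-based inclusive) is
read through gffutils and converted likewise.  All table writers prepend a
commented provenance header (config hash, seed, tool version) so every
output of the multi-stage filter pipeline is auditable.

Formats
-------
* per-algorithm call TSV: sample_id, chrom, start, end, type, n_probes,
  algorithm, platform
* sample manifest TSV: sample_id, status, sex, ancestry, platform,
  family_id, role
* trio TSV: proband_id, mother_id, father_id
* BED (3 cols, optional 4th label column) for stability maps and known loci
* GFF3 gene models with gene and CDS features
* GMT gene sets: one set per line — name, description, then gene ids
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

from . import __version__
from .consensus import CnvCall, StringentCnv
from .enrichment import GeneSet
from .intervals import GeneModel, GenomicInterval, IntervalSet

__all__ = [
    "read_calls",
    "write_calls",
    "read_manifest",
    "write_manifest",
    "read_trios",
    "write_trios",
    "read_bed",
    "write_bed",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_gmt",
    "write_gmt",
    "write_table",
    "validate_cohort",
    "calls_to_objects",
    "read_stringent",
    "write_stringent",
    "stringent_to_table",
    "table_to_stringent",
]

CALL_COLUMNS = ["sample_id", "chrom", "start", "end", "type", "n_probes",
                "algorithm", "platform"]
MANIFEST_COLUMNS = ["sample_id", "status", "sex", "ancestry", "platform",
                    "family_id", "role"]
TRIO_COLUMNS = ["proband_id", "mother_id", "father_id"]


def _provenance_header(meta: Mapping[str, object] | None) -> str:
    lines = [f"# cnvburden {__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def config_hash(config: Mapping[str, object]) -> str:
    text = "\n".join(f"{k}={config[k]}" for k in sorted(config))
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    """TSV with a commented provenance header block."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_header(meta))
        df.to_csv(fh, sep="\t", index=False)


def _read_table(path: str | Path, columns: Sequence[str], dtypes=None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=dtypes)
    except Exception as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_calls(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Per-algorithm CNV call table; converts to 0-based half-open if needed."""
    df = _read_table(path, CALL_COLUMNS, dtypes={"sample_id": str})
    if one_based:
        df = df.assign(start=df["start"] - 1)
    bad = df[(df["start"] < 0) | (df["end"] <= df["start"])]
    if len(bad):
        line = bad.index[0] + 2  # 1-based, after header
        raise ValueError(f"{path}:{line}: invalid interval "
                         f"[{bad.iloc[0]['start']}, {bad.iloc[0]['end']})")
    bad_type = ~df["type"].isin(["DEL", "DUP"])
    if bad_type.any():
        line = df.index[bad_type][0] + 2
        raise ValueError(f"{path}:{line}: type must be DEL or DUP")
    return df[CALL_COLUMNS]


def write_calls(df: pd.DataFrame, path: str | Path, meta=None) -> None:
    write_table(df[CALL_COLUMNS], path, meta)


def calls_to_objects(df: pd.DataFrame) -> dict[str, list[CnvCall]]:
    """Group a call table into per-sample :class:`CnvCall` lists."""
    out: dict[str, list[CnvCall]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.sample_id), []).append(
            CnvCall(
                sample_id=str(row.sample_id),
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                cnv_type=row.type,
                n_probes=int(row.n_probes),
                algorithm=row.algorithm,
                platform=row.platform,
            )
        )
    return out


STRINGENT_COLUMNS = ["sample_id", "chrom", "start", "end", "type", "n_probes",
                     "algorithms", "platform"]


def stringent_to_table(stringent: Mapping[str, Sequence[StringentCnv]]) -> pd.DataFrame:
    rows = []
    for sample in sorted(stringent):
        for cnv in sorted(stringent[sample]):
            rows.append(
                {
                    "sample_id": cnv.sample_id,
                    "chrom": cnv.interval.chrom,
                    "start": cnv.interval.start,
                    "end": cnv.interval.end,
                    "type": cnv.cnv_type,
                    "n_probes": cnv.n_probes,
                    "algorithms": ",".join(sorted(cnv.supporting_algorithms)),
                    "platform": cnv.platform,
                }
            )
    return pd.DataFrame(rows, columns=STRINGENT_COLUMNS)


def table_to_stringent(df: pd.DataFrame) -> dict[str, list[StringentCnv]]:
    out: dict[str, list[StringentCnv]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.sample_id), []).append(
            StringentCnv(
                sample_id=str(row.sample_id),
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                cnv_type=row.type,
                n_probes=int(row.n_probes),
                supporting_algorithms=frozenset(str(row.algorithms).split(",")),
                platform=row.platform,
            )
        )
    return out


def read_stringent(path: str | Path) -> dict[str, list[StringentCnv]]:
    return table_to_stringent(
        _read_table(path, STRINGENT_COLUMNS, dtypes={"sample_id": str})
    )


def write_stringent(
    stringent: Mapping[str, Sequence[StringentCnv]], path: str | Path, meta=None
) -> None:
    write_table(stringent_to_table(stringent), path, meta)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, MANIFEST_COLUMNS[:5], dtypes={"sample_id": str})
    for col in ("family_id", "role"):
        if col not in df.columns:
            df[col] = ""
    df[["family_id", "role"]] = df[["family_id", "role"]].fillna("")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    bad = ~df["status"].isin(["case", "control", "parent"])
    if bad.any():
        raise ValueError(
            f"{path}: status must be case/control/parent, got "
            f"{df.loc[bad, 'status'].iloc[0]!r}"
        )
    return df[MANIFEST_COLUMNS]


def write_manifest(df: pd.DataFrame, path: str | Path, meta=None) -> None:
    write_table(df[MANIFEST_COLUMNS], path, meta)


def read_trios(path: str | Path) -> pd.DataFrame:
    return _read_table(path, TRIO_COLUMNS, dtypes=str)


def write_trios(df: pd.DataFrame, path: str | Path, meta=None) -> None:
    write_table(df[TRIO_COLUMNS], path, meta)


def read_bed(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    """BED (0-based half-open): (label, interval) pairs; label "" if absent."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            label = parts[3] if len(parts) > 3 else ""
            out.append((label, iv))
    return out


def read_bed_intervals(path: str | Path) -> IntervalSet:
    return IntervalSet(iv for _, iv in read_bed(path))


def write_bed(
    entries: Iterable[tuple[str, GenomicInterval]] | IntervalSet,
    path: str | Path,
) -> None:
    if isinstance(entries, IntervalSet):
        entries = [("", iv) for iv in entries]
    with open(path, "w") as fh:
        for label, iv in entries:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if label:
                cols.append(label)
            fh.write("\t".join(cols) + "\n")


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Gene models with coding exons from GFF3 (1-based inclusive, converted).

    ``gene`` features define gene bodies (ID attribute is the identifier);
    ``CDS`` features with a Parent pointing at the gene (directly or via an
    mRNA) define coding exons.  Strand is ignored: CNV intersection is
    strandless.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gene_id = g.attributes.get("ID", [g.id])[0]
        exons = []
        for cds in db.children(g, featuretype="CDS"):
            exons.append(GenomicInterval(cds.seqid, cds.start - 1, cds.end))
        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=GenomicInterval(g.seqid, g.start - 1, g.end),
                exons=tuple(sorted(exons)),
            )
        )
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return genes


def write_gff3_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    """GFF3 with one gene and its CDS children (0-based converted to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t.\tgene\t{iv.start + 1}\t{iv.end}\t.\t.\t.\t"
                f"ID={g.gene_id}\n"
            )
            for k, ex in enumerate(g.exons):
                fh.write(
                    f"{ex.chrom}\t.\tCDS\t{ex.start + 1}\t{ex.end}\t.\t.\t0\t"
                    f"ID={g.gene_id}.cds{k};Parent={g.gene_id}\n"
                )


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Standard GMT: tab-separated set name, description, gene ids."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description, genes"
                )
            sets.append(GeneSet(name=parts[0], genes=frozenset(p for p in parts[2:] if p)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *sorted(gs.genes)]) + "\n")


def validate_cohort(
    calls: pd.DataFrame,
    manifest: pd.DataFrame,
    trios: pd.DataFrame | None = None,
) -> None:
    """Cross-file referential integrity: every referenced sample is known."""
    known = set(manifest["sample_id"].astype(str))
    unknown = set(calls["sample_id"].astype(str)) - known
    if unknown:
        raise ValueError(f"calls reference unknown samples: {sorted(unknown)[:5]}")
    if trios is not None and len(trios):
        members = (
            set(trios["proband_id"]) | set(trios["mother_id"]) | set(trios["father_id"])
        )
        unknown = members - known
        if unknown:
            raise ValueError(f"trios reference unknown samples: {sorted(unknown)[:5]}")
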