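"""Readers and writers for every external format the toolkit touches.

All tabular files are UTF-8, tab-separated, ``#``-prefixed comment lines are
ignored and the first non-comment line is a header.  Sequence data is plain
FASTA handled through Bio.SeqIO.  Computational modules never parse text
themselves; they consume the containers produced here.

Lineage tables come in Kaiju-flavoured dialects.  Kaiju emits ``NA`` for
ranks it cannot classify; the reader preserves those tokens verbatim (NA
propagation is a separate, explicit step in :mod:`magtk.taxonomy`).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, InputError
from .model import (
    NA_TOKEN,
    RANKS,
    ContigRecord,
    CoverageMatrix,
    GeneAnnotation,
    ModuleDefinition,
    SampleMeta,
)

#: Known lineage-table dialects.  Each maps a dialect name to the 0-based
#: column indices of (status, contig id, lineage); status is None when the
#: dialect has no classified/unclassified column.
LINEAGE_DIALECTS: dict[str, dict[str, int | None]] = {
    # Kaiju default output with -l lineage: status (C/U), read/contig id,
    # taxon id, semicolon-separated lineage.
    "kaiju3col+lineage": {"status": 0, "contig": 1, "lineage": 3},
    # Plain two-column table: contig id, lineage.
    "plain": {"status": None, "contig": 0, "lineage": 1},
}

DEFAULT_GENE_ID_PATTERN = r"^(?P<contig>.+)_\d+$"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, bin_id: str | None = None) -> list[ContigRecord]:
    """Read a FASTA file into contig records.

    The header token up to the first whitespace becomes the contig id.
    Raises on an empty file and on duplicate ids.
    """
    path = Path(path)
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        records.append(
            ContigRecord(contig_id=rec.id, length_bp=len(seq), sequence=seq, bin_id=bin_id)
        )
    if not records:
        raise FormatError(f"{path}: no sequences")
    return records


def write_fasta(
    contigs: Iterable[ContigRecord], path: str | Path, line_width: int = 60
) -> None:
    """Write contig records as FASTA with a configurable wrap width."""
    path = Path(path)
    seq_records = []
    for c in contigs:
        if c.sequence is None:
            raise InputError(f"contig {c.contig_id}: no sequence to write")
        seq_records.append(SeqRecord(Seq(c.sequence), id=c.contig_id, description=""))
    with open(path, "w", encoding="utf-8") as handle:
        writer = FastaWriter(handle, wrap=line_width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Lineage tables
# ---------------------------------------------------------------------------

def _split_lineage(raw: str) -> list[str]:
    parts = [p.strip() for p in raw.split(";")]
    # Kaiju appends a trailing "; " — drop empty tail fields only.
    while parts and parts[-1] == "":
        parts.pop()
    return parts


def _pad_lineage(parts: list[str]) -> tuple[str, ...]:
    """Coerce a split lineage to exactly ``len(RANKS)`` fields.

    Shorter lineages are padded at the tail with ``NA``; a longer lineage is
    assumed to carry leading super-rank fields (Kaiju's domain level), which
    are dropped.
    """
    n = len(RANKS)
    if len(parts) > n:
        parts = parts[len(parts) - n :]
    parts = [p if p else NA_TOKEN for p in parts]
    return tuple(parts + [NA_TOKEN] * (n - len(parts)))


def read_lineage_table(
    path: str | Path, dialect: str = "kaiju3col+lineage"
) -> dict[str, tuple[str, ...]]:
    """Read a per-contig lineage table in a Kaiju-style dialect.

    Returns a map contig id → raw lineage (``len(RANKS)`` strings, ``NA``
    allowed).  Contigs whose status column is ``U`` (unclassified) map to an
    all-NA lineage.
    """
    path = Path(path)
    if dialect not in LINEAGE_DIALECTS:
        raise InputError(
            f"unknown lineage dialect {dialect!r}; known: {sorted(LINEAGE_DIALECTS)}"
        )
    cols = LINEAGE_DIALECTS[dialect]
    status_col, contig_col, lineage_col = cols["status"], cols["contig"], cols["lineage"]
    min_fields = max(v for v in (status_col, contig_col) if v is not None) + 1

    out: dict[str, tuple[str, ...]] = {}
    header_seen = False
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise FormatError(f"{path}:{lineno}: expected ≥{min_fields} fields")
            contig_id = fields[contig_col].strip()
            if not contig_id:
                raise FormatError(f"{path}:{lineno}: empty contig id")
            if contig_id in out:
                raise FormatError(f"{path}:{lineno}: contig {contig_id!r} listed twice")
            unclassified = (
                status_col is not None
                and fields[status_col].strip().upper() == "U"
            )
            raw = fields[lineage_col] if lineage_col < len(fields) else ""
            if unclassified or not raw.strip():
                out[contig_id] = tuple([NA_TOKEN] * len(RANKS))
            else:
                out[contig_id] = _pad_lineage(_split_lineage(raw))
    if not header_seen:
        raise FormatError(f"{path}: empty lineage table")
    return out


def write_lineage_table(
    lineages: Mapping[str, Sequence[str]], path: str | Path, dialect: str = "plain"
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as handle:
        if dialect == "plain":
            handle.write("contig_id\tlineage\n")
            for contig_id, lin in lineages.items():
                handle.write(f"{contig_id}\t{'; '.join(lin)}\n")
        elif dialect == "kaiju3col+lineage":
            handle.write("status\tcontig_id\ttaxon_id\tlineage\n")
            for contig_id, lin in lineages.items():
                status = "U" if all(x == NA_TOKEN for x in lin) else "C"
                body = "" if status == "U" else "; ".join(lin)
                handle.write(f"{status}\t{contig_id}\t0\t{body}\n")
        else:
            raise InputError(f"unknown lineage dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Coverage tables
# ---------------------------------------------------------------------------

def read_coverage_table(
    path: str | Path, samples: Sequence[SampleMeta] | None = None
) -> CoverageMatrix:
    """Read a contig × sample coverage TSV into a raw CoverageMatrix.

    The first column holds contig ids; every other column is a sample.
    Blank cells are read as 0.  When sample metadata is supplied, every
    coverage column must be a known sample id.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={0: str}, float_precision="round_trip"
    )
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a contig column and ≥1 sample column")
    df = df.set_index(df.columns[0])
    df.index.name = "contig_id"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: contig {dup!r} listed twice")
    df = df.astype(float).fillna(0.0)
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative coverage values")
    if samples is not None:
        known = {s.sample_id for s in samples}
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise InputError(
                f"{path}: sample column(s) {unknown} absent from metadata"
            )
    return CoverageMatrix(values=df, state="raw")


def write_coverage_table(
    matrix: CoverageMatrix, path: str | Path, comments: Sequence[str] = ()
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as handle:
        for line in comments:
            handle.write(f"# {line}\n")
        matrix.values.to_csv(handle, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> list[SampleMeta]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    required = {"sample_id", "role", "depth_cm", "total_mapped_reads"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return [
        SampleMeta(
            sample_id=str(r.sample_id),
            role=str(r.role),
            depth_cm=float(r.depth_cm),
            total_mapped_reads=int(r.total_mapped_reads),
        )
        for r in df.itertuples()
    ]


def write_sample_table(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "role": s.role,
                "depth_cm": s.depth_cm,
                "total_mapped_reads": s.total_mapped_reads,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# KO annotations
# ---------------------------------------------------------------------------

def read_ko_table(
    path: str | Path,
    gene_id_pattern: str = DEFAULT_GENE_ID_PATTERN,
    contig_map: Mapping[str, str] | None = None,
) -> list[GeneAnnotation]:
    """Read a two-column gene → KO table (GhostKOALA-style).

    The contig id is derived from the gene id either through an explicit
    ``contig_map`` or by the ``gene_id_pattern`` regex whose ``contig`` group
    captures the contig id (default: strip a final ``_<integer>`` suffix, the
    Prodigal convention).  Rows with an empty KO field are retained with
    ``ko_id`` absent.
    """
    path = Path(path)
    pattern = re.compile(gene_id_pattern)
    annotations: list[GeneAnnotation] = []
    header_seen = False
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            fields = line.split("\t")
            gene_id = fields[0].strip()
            ko = fields[1].strip() if len(fields) > 1 else ""
            if contig_map is not None and gene_id in contig_map:
                contig_id = contig_map[gene_id]
            else:
                m = pattern.match(gene_id)
                if m is None:
                    raise FormatError(
                        f"{path}:{lineno}: gene id {gene_id!r} does not match "
                        f"pattern {gene_id_pattern!r}"
                    )
                contig_id = m.group("contig")
            annotations.append(
                GeneAnnotation(gene_id=gene_id, contig_id=contig_id, ko_id=ko or None)
            )
    return annotations


def write_ko_table(annotations: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("gene_id\tko_id\n")
        for a in annotations:
            handle.write(f"{a.gene_id}\t{a.ko_id or ''}\n")


# ---------------------------------------------------------------------------
# KEGG Module definitions
# ---------------------------------------------------------------------------

def read_module_definitions(path: str | Path) -> list[ModuleDefinition]:
    """Read module definitions: module id, then comma/whitespace-separated KOs.

    Duplicate KOs within a module collapse; a module with zero KOs is an
    error.
    """
    path = Path(path)
    modules: list[ModuleDefinition] = []
    seen: set[str] = set()
    header_seen = False
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            fields = line.split("\t", 1)
            module_id = fields[0].strip()
            kos = re.split(r"[,\s]+", fields[1].strip()) if len(fields) > 1 else []
            kos = [k for k in kos if k]
            if not kos:
                raise FormatError(f"{path}:{lineno}: module {module_id!r} has zero KOs")
            if module_id in seen:
                raise FormatError(f"{path}:{lineno}: module {module_id!r} listed twice")
            seen.add(module_id)
            modules.append(ModuleDefinition(module_id=module_id, ko_ids=frozenset(kos)))
    return modules


def write_module_definitions(modules: Sequence[ModuleDefinition], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("module_id\tko_ids\n")
        for m in modules:
            handle.write(f"{m.module_id}\t{','.join(sorted(m.ko_ids))}\n")


# ---------------------------------------------------------------------------
# MAG membership
# ---------------------------------------------------------------------------

def read_mag_table(path: str | Path) -> dict[str, str]:
    """Read a contig → MAG membership TSV (columns contig_id, mag_id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"contig_id", "mag_id"}.issubset(df.columns):
        raise FormatError(f"{path}: need columns contig_id, mag_id")
    if df["contig_id"].duplicated().any():
        dup = df.loc[df["contig_id"].duplicated(), "contig_id"].iloc[0]
        raise FormatError(f"{path}: contig {dup!r} assigned to more than one MAG")
    return dict(zip(df["contig_id"], df["mag_id"]))


def write_mag_table(membership: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"contig_id": list(membership), "mag_id": list(membership.values())}
    ).to_csv(path, sep="\t", index=False)
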