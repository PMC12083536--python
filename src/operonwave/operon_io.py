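"""Operon annotation, expression-table and region-count I/O plus structural statistics.

The central container is :class:`GenomeAnnotation`: ordered genes grouped into
operons, promoter (TSS) records mapped to the first gene they can transcribe,
and terminator (TTS) records.  Coordinate conventions follow RegulonDB: genomic
coordinates are 1-based inclusive; a gene's *position* ``P`` is its 1-based
gene-unit index within its operon counted from the operon's 5' (most upstream)
gene.  Minus-strand operons are ordered 5'->3' along their own strand, i.e.
position 1 is the gene with the largest genomic coordinate.

Expression tables (per-gene log2 fold changes with p-values) and region
read-count tables (start/end read counts per gene per replicate) are plain
:class:`pandas.DataFrame` objects with validated column sets, the way DESeq2
and featureCounts outputs are normally consumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EXPRESSION_COLUMNS = ["gene_id", "condition_id", "lfc", "p_value"]
REGION_COLUMNS = ["gene_id", "replicate_id", "condition_id", "reads_start", "reads_end"]

#: accepted aliases for expression-table columns (DESeq2 output headers)
_EXPR_ALIASES = {
    "gene_id": ("gene_id", "gene", "id", "gene_name"),
    "lfc": ("lfc", "log2foldchange", "log2fc", "lfc_log2"),
    "p_value": ("p_value", "pvalue", "padj", "p"),
    "condition_id": ("condition_id", "condition", "contrast"),
}


class AnnotationError(ValueError):
    """Raised when an annotation table violates a structural invariant."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene inside (or outside) an operon.

    ``position`` is the 1-based gene-unit index within the operon (1 = most
    upstream gene on the operon strand); ``None`` for genes outside operons.
    """

    gene_id: str
    operon_id: str | None
    position: int | None
    start_nt: int
    end_nt: int
    strand: str
    length_nt: int = 0

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.end_nt < self.start_nt:
            raise AnnotationError(f"{self.gene_id}: end_nt < start_nt")
        if self.length_nt == 0:
            object.__setattr__(self, "length_nt", self.end_nt - self.start_nt + 1)

    @property
    def tss_side_nt(self) -> int:
        """Genomic coordinate of the gene's 5' (coding-start) end."""
        return self.start_nt if self.strand == "+" else self.end_nt

    @property
    def tes_side_nt(self) -> int:
        """Genomic coordinate of the gene's 3' end."""
        return self.end_nt if self.strand == "+" else self.start_nt


@dataclass(frozen=True)
class PromoterRecord:
    """A promoter, located by its TSS, mapped to the first gene it transcribes."""

    promoter_id: str
    operon_id: str
    tss_nt: int
    first_gene_index: int
    sigma_preference: str | None = None
    synthesized: bool = False

    @property
    def is_internal(self) -> bool:
        return self.first_gene_index > 1


@dataclass(frozen=True)
class TerminatorRecord:
    """A transcription termination site (TTS)."""

    tts_nt: int
    operon_id: str | None = None
    within_gene_id: str | None = None

    @property
    def intergenic(self) -> bool:
        return self.within_gene_id is None


@dataclass
class GeneSet:
    name: str
    members: set[str]

    def validate(self, annotation: "GenomeAnnotation") -> None:
        unknown = self.members - set(annotation.gene_index)
        if unknown:
            raise AnnotationError(f"gene set {self.name!r} has unknown genes: {sorted(unknown)[:5]}")


@dataclass
class GenomeAnnotation:
    """Validated operon annotation of a (circular) bacterial genome."""

    genes: list[GeneRecord]
    promoters: list[PromoterRecord]
    terminators: list[TerminatorRecord]
    genome_length_nt: int
    report: dict = field(default_factory=dict)

    # -- derived indexes -------------------------------------------------
    def __post_init__(self):
        self._rebuild_indexes()

    def _rebuild_indexes(self) -> None:
        self.gene_index: dict[str, GeneRecord] = {}
        for g in self.genes:
            if g.gene_id in self.gene_index:
                raise AnnotationError(f"duplicate gene id {g.gene_id!r}")
            self.gene_index[g.gene_id] = g
        self.operons: dict[str, list[str]] = {}
        for g in sorted(
            (g for g in self.genes if g.operon_id is not None),
            key=lambda g: (g.operon_id, g.position),
        ):
            self.operons.setdefault(g.operon_id, []).append(g.gene_id)
        for oid, gids in self.operons.items():
            pos = [self.gene_index[g].position for g in gids]
            if pos != list(range(1, len(gids) + 1)):
                raise AnnotationError(f"operon {oid}: positions are not consecutive 1..n ({pos})")
        self.promoters_by_operon: dict[str, list[PromoterRecord]] = {}
        for p in self.promoters:
            if p.operon_id not in self.operons:
                raise AnnotationError(f"promoter {p.promoter_id}: unknown operon {p.operon_id}")
            n = len(self.operons[p.operon_id])
            if not 1 <= p.first_gene_index <= n:
                raise AnnotationError(
                    f"promoter {p.promoter_id}: first_gene_index {p.first_gene_index} outside 1..{n}"
                )
            self.promoters_by_operon.setdefault(p.operon_id, []).append(p)
        for plist in self.promoters_by_operon.values():
            plist.sort(key=lambda p: p.first_gene_index)
        for t in self.terminators:
            if not 1 <= t.tts_nt <= self.genome_length_nt:
                raise AnnotationError(f"terminator at {t.tts_nt} outside genome span")

    # -- convenience -----------------------------------------------------
    def operon_genes(self, operon_id: str) -> list[GeneRecord]:
        return [self.gene_index[g] for g in self.operons[operon_id]]

    def operon_size(self, operon_id: str) -> int:
        return len(self.operons[operon_id])

    def internal_promoters(self, operon_id: str) -> list[PromoterRecord]:
        return [p for p in self.promoters_by_operon.get(operon_id, []) if p.is_internal]

    def n_operon_genes(self) -> int:
        return sum(len(g) for g in self.operons.values())

    def internal_tss_between(self, operon_id: str, i: int, j: int) -> int:
        """Number of promoters with first_gene_index in (i, j] for positions i < j.

        At L_G = 1 this counts a TSS in the intergenic region between two
        adjacent genes (the "one internal TSS in between" convention).
        """
        if i > j:
            i, j = j, i
        return sum(
            1 for p in self.promoters_by_operon.get(operon_id, []) if i < p.first_gene_index <= j
        )

    def copy(self) -> "GenomeAnnotation":
        return GenomeAnnotation(
            genes=list(self.genes),
            promoters=list(self.promoters),
            terminators=list(self.terminators),
            genome_length_nt=self.genome_length_nt,
            report=dict(self.report),
        )


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

def assign_first_gene_index(genes: Sequence[GeneRecord], tss_nt: int) -> int | None:
    """Index (1-based) of the first gene whose coding start is strictly downstream of the TSS.

    ``genes`` must be the operon's genes ordered by position.  Returns ``None``
    when the TSS lies downstream of every coding start on the operon strand.
    """
    strand = genes[0].strand
    for g in genes:
        downstream = g.tss_side_nt > tss_nt if strand == "+" else g.tss_side_nt < tss_nt
        if downstream:
            return g.position
    return None


def parse_annotation(path: str | Path, *, synthesize_primary: bool = True) -> GenomeAnnotation:
    """Parse a tab-separated annotation table into a :class:`GenomeAnnotation`.

    The dialect has a header and one row per feature::

        feature  id  operon_id  start  end  strand  attributes

    ``feature`` is one of ``gene``, ``promoter``, ``terminator``.  For
    promoters, ``start`` is the TSS coordinate; for terminators, the TTS
    coordinate.  ``attributes`` is a ``key=value;...`` string (recognised keys:
    ``sigma``, ``within_gene``, ``genome_length``).  A promoter whose TSS lies
    downstream of all coding starts of its operon is dropped with a warning.
    Operons without any promoter at gene 1 get a synthesized primary promoter
    (flagged in the report) unless ``synthesize_primary`` is false.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"feature", "id", "operon_id", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"annotation table missing columns: {sorted(missing)}")

    report: dict = {"dropped_promoters": [], "synthesized_primaries": [], "warnings": []}
    genome_length = 0

    gene_rows = df[df["feature"] == "gene"]
    seen: dict[str, str] = {}
    raw_genes: list[dict] = []
    for _, row in gene_rows.iterrows():
        gid = row["id"]
        oid = row["operon_id"] or None
        if gid in seen:
            if seen[gid] != oid:
                raise AnnotationError(f"gene {gid!r} listed in two operons ({seen[gid]!r}, {oid!r})")
            raise AnnotationError(f"duplicate gene id {gid!r}")
        seen[gid] = oid
        raw_genes.append(
            dict(gene_id=gid, operon_id=oid, start=int(row["start"]), end=int(row["end"]), strand=row["strand"])
        )
        genome_length = max(genome_length, int(row["end"]))

    attrs = _parse_attrs(df)
    for a in attrs:
        if "genome_length" in a:
            genome_length = max(genome_length, int(a["genome_length"]))

    genes = _order_genes(raw_genes)
    by_operon: dict[str, list[GeneRecord]] = {}
    for g in genes:
        if g.operon_id:
            by_operon.setdefault(g.operon_id, []).append(g)
    for gl in by_operon.values():
        gl.sort(key=lambda g: g.position)

    promoters: list[PromoterRecord] = []
    for idx, row in df[df["feature"] == "promoter"].iterrows():
        oid = row["operon_id"]
        if oid not in by_operon:
            raise AnnotationError(f"promoter {row['id']!r}: unknown operon {oid!r}")
        a = _parse_attr_string(row.get("attributes", ""))
        tss = int(row["start"])
        fg = assign_first_gene_index(by_operon[oid], tss)
        if fg is None:
            report["dropped_promoters"].append(row["id"])
            logger.warning("promoter %s: TSS downstream of all coding starts; dropped", row["id"])
            continue
        promoters.append(
            PromoterRecord(
                promoter_id=row["id"], operon_id=oid, tss_nt=tss,
                first_gene_index=fg, sigma_preference=a.get("sigma"),
            )
        )

    terminators: list[TerminatorRecord] = []
    for _, row in df[df["feature"] == "terminator"].iterrows():
        a = _parse_attr_string(row.get("attributes", ""))
        terminators.append(
            TerminatorRecord(
                tts_nt=int(row["start"]),
                operon_id=row["operon_id"] or None,
                within_gene_id=a.get("within_gene") or None,
            )
        )
        genome_length = max(genome_length, int(row["start"]))

    # synthesize missing primary promoters
    have_primary = {p.operon_id for p in promoters if p.first_gene_index == 1}
    for oid, gl in by_operon.items():
        if oid not in have_primary:
            if not synthesize_primary:
                raise AnnotationError(f"operon {oid}: no primary promoter")
            first = gl[0]
            tss = first.tss_side_nt - 1 if first.strand == "+" else first.tss_side_nt + 1
            promoters.append(
                PromoterRecord(
                    promoter_id=f"{oid}_p_primary_synth", operon_id=oid, tss_nt=max(tss, 1),
                    first_gene_index=1, synthesized=True,
                )
            )
            report["synthesized_primaries"].append(oid)
            logger.warning("operon %s: missing primary promoter; synthesized at gene 1", oid)

    return GenomeAnnotation(
        genes=genes, promoters=promoters, terminators=terminators,
        genome_length_nt=genome_length, report=report,
    )


def _parse_attrs(df: pd.DataFrame) -> list[dict]:
    if "attributes" not in df.columns:
        return []
    return [_parse_attr_string(s) for s in df["attributes"]]


def _parse_attr_string(s: str | float) -> dict:
    if not isinstance(s, str) or not s.strip():
        return {}
    out = {}
    for part in s.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _order_genes(raw: list[dict]) -> list[GeneRecord]:
    """Assign within-operon positions by coordinate order along the operon strand."""
    genes: list[GeneRecord] = []
    by_operon: dict[str, list[dict]] = {}
    for r in raw:
        if r["operon_id"] is None:
            genes.append(
                GeneRecord(r["gene_id"], None, None, r["start"], r["end"], r["strand"])
            )
        else:
            by_operon.setdefault(r["operon_id"], []).append(r)
    for oid, rows in by_operon.items():
        strands = {r["strand"] for r in rows}
        if len(strands) > 1:
            raise AnnotationError(f"operon {oid}: mixed strands")
        rows.sort(key=lambda r: r["start"], reverse=(rows[0]["strand"] == "-"))
        for pos, r in enumerate(rows, start=1):
            genes.append(
                GeneRecord(r["gene_id"], oid, pos, r["start"], r["end"], r["strand"])
            )
    return genes


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write the tab-separated dialect read by :func:`parse_annotation` (round-trip safe)."""
    rows = []
    for g in annotation.genes:
        rows.append(
            dict(feature="gene", id=g.gene_id, operon_id=g.operon_id or "",
                 start=g.start_nt, end=g.end_nt, strand=g.strand,
                 attributes=f"genome_length={annotation.genome_length_nt}")
        )
    for p in annotation.promoters:
        if p.synthesized:
            continue  # synthesized primaries are parse artifacts, re-created on read
        attrs = f"sigma={p.sigma_preference}" if p.sigma_preference else ""
        g1 = annotation.operon_genes(p.operon_id)[0]
        rows.append(
            dict(feature="promoter", id=p.promoter_id, operon_id=p.operon_id,
                 start=p.tss_nt, end=p.tss_nt, strand=g1.strand, attributes=attrs)
        )
    for i, t in enumerate(annotation.terminators):
        attrs = f"within_gene={t.within_gene_id}" if t.within_gene_id else ""
        rows.append(
            dict(feature="terminator", id=f"tts_{i}", operon_id=t.operon_id or "",
                 start=t.tts_nt, end=t.tts_nt, strand="+", attributes=attrs)
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def parse_gff3(path: str | Path) -> GenomeAnnotation:
    """Minimal GFF3 reader mapping ``gene``/``promoter``/``terminator`` features.

    Operon membership is taken from an ``operon_id`` attribute (or ``Parent``).
    """
    rows = []
    genome_length = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                genome_length = int(line.split()[-1])
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                continue
            attrs = {k: v for k, v in (kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)}
            if f[2] not in ("gene", "promoter", "terminator"):
                continue
            rows.append(
                dict(feature=f[2], id=attrs.get("ID", f"{f[2]}_{len(rows)}"),
                     operon_id=attrs.get("operon_id", attrs.get("Parent", "")),
                     start=f[3], end=f[4], strand=f[6] if f[6] in "+-" else "+",
                     attributes=f"genome_length={genome_length}" if genome_length else "")
            )
    import os
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as tmp:
        pd.DataFrame(rows).to_csv(tmp, sep="\t", index=False)
        name = tmp.name
    try:
        return parse_annotation(name)
    finally:
        os.unlink(name)


# ---------------------------------------------------------------------------
# expression and count tables
# ---------------------------------------------------------------------------

def read_expression_table(
    path: str | Path, *, condition_id: str | None = None,
    annotation: GenomeAnnotation | None = None,
) -> pd.DataFrame:
    """Read a DESeq2-style TSV (gene_id, log2FoldChange, pvalue [, condition]).

    Rows with non-parseable ``NA`` fold changes are dropped and logged; a
    non-numeric non-NA value raises with the offending row index.  Genes absent
    from ``annotation`` (when given) are retained but flagged in the
    ``in_annotation`` column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    colmap = {}
    for canon, aliases in _EXPR_ALIASES.items():
        for a in aliases:
            if a in df.columns:
                colmap[canon] = a
                break
    for req in ("gene_id", "lfc"):
        if req not in colmap:
            raise ValueError(f"expression table lacks a {req} column (have {list(df.columns)})")
    out = pd.DataFrame({"gene_id": df[colmap["gene_id"]].astype(str)})
    raw_lfc = df[colmap["lfc"]]
    lfc = pd.to_numeric(raw_lfc, errors="coerce")
    na_like = raw_lfc.isna() | raw_lfc.astype(str).str.strip().str.upper().isin(["NA", "NAN", ""])
    bad = lfc.isna() & ~na_like
    if bad.any():
        raise ValueError(f"non-numeric lfc at row(s) {list(df.index[bad])[:5]}")
    out["lfc"] = lfc
    out["p_value"] = pd.to_numeric(df[colmap["p_value"]], errors="coerce") if "p_value" in colmap else np.nan
    out["condition_id"] = df[colmap["condition_id"]] if "condition_id" in colmap else (condition_id or "stress")
    n_dropped = int(out["lfc"].isna().sum())
    if n_dropped:
        logger.info("dropped %d rows with missing LFC", n_dropped)
    out = out.dropna(subset=["lfc"]).reset_index(drop=True)
    dup = out.duplicated(subset=["gene_id", "condition_id"])
    if dup.any():
        raise ValueError(f"duplicate (gene, condition) rows: {out.loc[dup, 'gene_id'].tolist()[:5]}")
    if annotation is not None:
        out["in_annotation"] = out["gene_id"].isin(annotation.gene_index).values
        n_out = int((~out["in_annotation"]).sum())
        if n_out:
            logger.info("%d expression rows for genes absent from annotation (retained, flagged)", n_out)
    validate_expression(out)
    out.attrs["n_dropped"] = n_dropped
    return out


def validate_expression(df: pd.DataFrame) -> None:
    for c in ("gene_id", "condition_id", "lfc"):
        if c not in df.columns:
            raise ValueError(f"expression table missing column {c!r}")
    if not np.isfinite(df["lfc"].to_numpy(float)).all():
        raise ValueError("non-finite LFC values present")
    if df.duplicated(subset=["gene_id", "condition_id"]).any():
        raise ValueError("duplicate (gene, condition) rows")


def read_region_counts(path: str | Path) -> pd.DataFrame:
    """Read a featureCounts-style start/end region count TSV.

    Columns: gene_id, replicate, condition, reads_start, reads_end (aliases
    ``replicate_id``/``condition_id`` accepted).  Negative counts raise;
    conditions with unbalanced replicate sets get a warning.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    df = df.rename(columns={"replicate": "replicate_id", "condition": "condition_id"})
    missing = set(REGION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"region count table missing columns: {sorted(missing)}")
    df = df[REGION_COLUMNS].copy()
    df["gene_id"] = df["gene_id"].astype(str)
    for c in ("reads_start", "reads_end"):
        df[c] = pd.to_numeric(df[c])
        if (df[c] < 0).any():
            raise ValueError(f"negative counts in column {c}")
    reps = df.groupby("condition_id")["replicate_id"].nunique()
    per_gene = df.groupby(["condition_id", "gene_id"])["replicate_id"].nunique()
    expected = per_gene.index.get_level_values(0).map(reps)
    if (per_gene.to_numpy() != expected.to_numpy()).any():
        logger.warning("some genes are missing replicates in at least one condition")
    return df


def read_gene_sets(path: str | Path) -> dict[str, GeneSet]:
    """Read gene sets from a two-column TSV (set_name, gene_id)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "gene_id"], comment="!")
    return {
        name: GeneSet(name=name, members=set(sub["gene_id"].astype(str)))
        for name, sub in df.groupby("name")
    }


def read_go_map(path: str | Path) -> dict[str, list[str]]:
    """Read a gene->GO-term map from a 2-column TSV or a GAF-like file.

    Lines starting with ``!`` are comments.  Rows with >= 5 tab-separated
    fields are treated as GAF (gene symbol in column 2, term in column 5).
    """
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            gene, term = (f[2], f[4]) if len(f) >= 5 else (f[0], f[1])
            out.setdefault(gene, [])
            if term not in out[gene]:
                out[gene].append(term)
    return out


def write_go_map(go_map: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, terms in go_map.items():
            for t in terms:
                fh.write(f"{gene}\t{t}\n")


# ---------------------------------------------------------------------------
# structural statistics
# ---------------------------------------------------------------------------

def structural_summary(annotation: GenomeAnnotation) -> pd.DataFrame:
    """Per-operon structural statistics.

    Columns: gene count, nucleotide length (5' start of first gene to 3' end of
    last), mean intergenic distance (nt), TSS count and internal-TSS count.
    Genome-wide aggregates are stored in ``df.attrs['genome']``.
    """
    rows = []
    for oid, gids in annotation.operons.items():
        genes = annotation.operon_genes(oid)
        starts = [g.start_nt for g in genes]
        ends = [g.end_nt for g in genes]
        length = max(ends) - min(starts) + 1
        inter = []
        for a, b in zip(genes[:-1], genes[1:]):
            if genes[0].strand == "+":
                inter.append(b.start_nt - a.end_nt - 1)
            else:
                inter.append(a.start_nt - b.end_nt - 1)
        proms = annotation.promoters_by_operon.get(oid, [])
        rows.append(
            dict(operon_id=oid, n_genes=len(genes), length_nt=length,
                 mean_intergenic_nt=float(np.mean(inter)) if inter else np.nan,
                 n_tss=len(proms), n_internal_tss=sum(p.is_internal for p in proms))
        )
    df = pd.DataFrame(rows).set_index("operon_id")
    all_inter = df["mean_intergenic_nt"].dropna()
    df.attrs["genome"] = dict(
        n_operons=len(df),
        n_operon_genes=int(df["n_genes"].sum()),
        n_tss=int(df["n_tss"].sum()),
        n_internal_tss=int(df["n_internal_tss"].sum()),
        mean_intergenic_nt=float(all_inter.mean()) if len(all_inter) else np.nan,
        median_operon_size=float(df["n_genes"].median()),
    )
    return df


def downstream_gap_stats(annotation: GenomeAnnotation) -> dict:
    """Distance from each operon's 3' end to the next downstream gene, split by TTS presence.

    The gap is measured along the operon's strand to the 5' start of the
    nearest gene downstream of the operon end; the genome is treated as
    circular, so the last operon wraps around.  Groups are compared with a
    two-sample equal-variance t test.
    """
    L = annotation.genome_length_nt
    tts_pos = np.array(sorted(t.tts_nt for t in annotation.terminators))
    gene_5p = np.array(sorted(g.tss_side_nt for g in annotation.genes))
    rows = []
    for oid in annotation.operons:
        genes = annotation.operon_genes(oid)
        strand = genes[0].strand
        end3 = max(g.end_nt for g in genes) if strand == "+" else min(g.start_nt for g in genes)
        own = {g.gene_id for g in genes}
        others = np.array(sorted(g.tss_side_nt for g in annotation.genes if g.gene_id not in own))
        if len(others) == 0:
            continue
        if strand == "+":
            ahead = others[others > end3]
            nxt = ahead[0] if len(ahead) else others[0] + L  # circular wrap
            gap = nxt - end3 - 1
            lo, hi = end3, (nxt if len(ahead) else others[0] + L)
            has_tts = _tts_in_interval(tts_pos, lo, hi, L)
        else:
            behind = others[others < end3]
            nxt = behind[-1] if len(behind) else others[-1] - L
            gap = end3 - nxt - 1
            lo, hi = (nxt if len(behind) else others[-1] - L), end3
            has_tts = _tts_in_interval(tts_pos, lo, hi, L)
        rows.append(dict(operon_id=oid, gap_nt=int(gap), has_tts=bool(has_tts)))
    df = pd.DataFrame(rows)
    with_t = df.loc[df["has_tts"], "gap_nt"].to_numpy(float)
    without = df.loc[~df["has_tts"], "gap_nt"].to_numpy(float)
    res: dict = {
        "gaps": df,
        "mean_with_tts": float(with_t.mean()) if len(with_t) else np.nan,
        "mean_without_tts": float(without.mean()) if len(without) else np.nan,
        "n_with_tts": len(with_t),
        "n_without_tts": len(without),
    }
    if len(with_t) and len(without):
        res["ratio_without_over_with"] = res["mean_without_tts"] / res["mean_with_tts"]
        res["p_value"] = float(stats.ttest_ind(with_t, without, equal_var=True).pvalue)
    else:
        res["ratio_without_over_with"] = np.nan
        res["p_value"] = np.nan
    return res


def _tts_in_interval(tts_pos: np.ndarray, lo: float, hi: float, genome_len: int) -> bool:
    if len(tts_pos) == 0:
        return False
    # interval may extend beyond [1, L] due to circular wrap
    for shift in (-genome_len, 0, genome_len):
        p = tts_pos + shift
        if np.any((p > lo) & (p < hi)):
            return True
    return False


def tss_uniform_null(
    annotation: GenomeAnnotation, n_draws: int = 1000, seed: int | None = None,
    n_length_bins: int = 5,
) -> pd.DataFrame:
    """Observed internal-TSS counts per operon-length bin vs a uniform-placement null.

    The null keeps the genome-wide internal-TSS budget and drops each TSS
    uniformly over the concatenated nucleotide spans of all operons; a TSS
    lands in the operon whose span contains it.  Per length bin, the returned
    table holds the observed count, the null mean/sd and the empirical quantile
    of the observed count within the null (mid-rank convention).
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    rng = np.random.default_rng(seed)
    summ = structural_summary(annotation)
    summ = summ[summ["length_nt"] > 0]
    n_internal = int(summ["n_internal_tss"].sum())
    lengths = summ["length_nt"].to_numpy(float)
    # quantile bins over operon nt length; duplicate edges (tied lengths) collapse
    qs = np.quantile(lengths, np.linspace(0, 1, n_length_bins + 1))
    qs[-1] += 1
    edges = np.unique(qs)
    if len(edges) == 1:
        edges = np.array([edges[0] - 1, edges[0]])
    n_length_bins = len(edges) - 1
    bin_of = np.clip(np.digitize(lengths, edges) - 1, 0, n_length_bins - 1)
    observed = np.array(
        [summ["n_internal_tss"].to_numpy()[bin_of == b].sum() for b in range(n_length_bins)]
    )
    probs = lengths / lengths.sum()
    null_counts = np.zeros((n_draws, n_length_bins))
    for d in range(n_draws):
        placed = rng.multinomial(n_internal, probs)
        for b in range(n_length_bins):
            null_counts[d, b] = placed[bin_of == b].sum()
    less = (null_counts < observed).mean(axis=0)
    equal = (null_counts == observed).mean(axis=0)
    quant = less + 0.5 * equal
    return pd.DataFrame(
        dict(
            length_bin_lo=edges[:-1], length_bin_hi=edges[1:],
            observed=observed, null_mean=null_counts.mean(axis=0),
            null_sd=null_counts.std(axis=0, ddof=1), quantile=quant,
        )
    )
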