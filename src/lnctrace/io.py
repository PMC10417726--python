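"""Readers and writers for the external formats the pipeline touches.

Formats: GTF (genes + exons), GMT gene-set collections, gene-level count
matrices (TSV or MatrixMarket triplet with ``.rownames``/``.colnames``
sidecars), sample sheets, and parameterised TSV result tables.

Conventions
-----------
Internal genomic coordinates are 0-based half-open; GTF I/O converts at the
boundary (GTF is 1-based inclusive).  Gene biotype is read from
``gene_biotype`` with a fallback to ``gene_type``; anything that is not
``protein_coding``/``lncRNA`` (or the reserved ``spike_in``) maps to
``other`` so GENCODE/Ensembl dialect differences are tolerated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

from .errors import ParseError, ReconciliationError, ValidationError

GENOTYPES = ("WT", "KO")
CONDITIONS = ("tumor", "tumor_free")
TIMEPOINTS = (6, 8, 10, 12)
BIOTYPES = ("protein_coding", "lncRNA", "spike_in", "other")

SAMPLESHEET_COLUMNS = ["sample_id", "genotype", "condition", "timepoint_weeks", "replicate"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus: 0-based half-open span, strand, biotype, optional exons."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    exons: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or not self.start < self.end:
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"gene {self.gene_id}: bad biotype {self.biotype!r}")
        if self.exons is not None:
            exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
            for s, e in exons:
                if not (self.start <= s < e <= self.end):
                    raise ValidationError(
                        f"gene {self.gene_id}: exon [{s}, {e}) outside gene span"
                    )
            for (_, e0), (s1, _) in zip(exons, exons[1:]):
                if s1 < e0:
                    raise ValidationError(f"gene {self.gene_id}: overlapping exons")
            object.__setattr__(self, "exons", exons)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start: 5' end of the span, strand-aware."""
        return self.start if self.strand == "+" else self.end - 1


class GeneAnnotations:
    """An ordered, id-unique collection of :class:`GeneAnnotation`."""

    def __init__(self, genes: Iterable[GeneAnnotation]):
        self._genes: dict[str, GeneAnnotation] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            self._genes[g.gene_id] = g

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneAnnotation]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneAnnotation:
        return self._genes[gene_id]

    @property
    def ids(self) -> list[str]:
        return list(self._genes)

    def get(self, gene_id: str, default=None):
        return self._genes.get(gene_id, default)

    def by_chrom(self) -> dict[str, list[GeneAnnotation]]:
        out: dict[str, list[GeneAnnotation]] = {}
        for g in self:
            out.setdefault(g.chrom, []).append(g)
        for genes in out.values():
            genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        return out

    def subset(self, gene_ids: Iterable[str]) -> "GeneAnnotations":
        return GeneAnnotations(self._genes[g] for g in gene_ids)


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced library of the lineage-traced tumor study design."""

    sample_id: str
    genotype: str
    condition: str
    timepoint_weeks: int
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"{self.sample_id}: genotype must be one of {GENOTYPES}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"{self.sample_id}: condition must be one of {CONDITIONS}")
        if self.timepoint_weeks not in TIMEPOINTS:
            raise ValidationError(
                f"{self.sample_id}: timepoint_weeks must be one of {TIMEPOINTS}"
            )
        if self.replicate < 1:
            raise ValidationError(f"{self.sample_id}: replicate must be >= 1")

    @property
    def group(self) -> tuple[str, str, int]:
        return (self.genotype, self.condition, self.timepoint_weeks)


class CountMatrix:
    """Gene x sample matrix of non-negative integer counts plus metadata."""

    def __init__(self, gene_ids: Sequence[str], samples: Sequence[SampleRecord], counts):
        counts = np.asarray(counts)
        if counts.shape != (len(gene_ids), len(samples)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(gene_ids)} genes x {len(samples)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            frac, _ = np.modf(counts)
            if np.any(frac != 0):
                g, s = np.argwhere(frac != 0)[0]
                raise ValidationError(
                    f"non-integer count at gene {gene_ids[g]!r}, "
                    f"sample {samples[s].sample_id!r}"
                )
        if counts.size and counts.min() < 0:
            g, s = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {gene_ids[g]!r}, sample {samples[s].sample_id!r}"
            )
        if len(set(gene_ids)) != len(gene_ids):
            raise ValidationError("duplicate gene_ids in count matrix")
        keys = [s.sample_id for s in samples]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate sample_ids")
        groups = [(s.genotype, s.condition, s.timepoint_weeks, s.replicate) for s in samples]
        if len(set(groups)) != len(groups):
            raise ValidationError("duplicate (genotype, condition, timepoint, replicate)")
        self.gene_ids = list(gene_ids)
        self.samples = list(samples)
        self.counts = counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in count matrix") from None

    def gene_counts(self, gene_id: str) -> np.ndarray:
        return self.counts[self.gene_index(gene_id)]

    def select_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.gene_index(g) for g in gene_ids]
        return CountMatrix(list(gene_ids), self.samples, self.counts[idx])

    def select_samples(self, mask_or_ids) -> "CountMatrix":
        if all(isinstance(x, (bool, np.bool_)) for x in mask_or_ids):
            idx = [i for i, keep in enumerate(mask_or_ids) if keep]
        else:
            order = {sid: i for i, sid in enumerate(self.sample_ids)}
            idx = [order[sid] for sid in mask_or_ids]
        return CountMatrix(self.gene_ids, [self.samples[i] for i in idx],
                           self.counts[:, idx])


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"gene set {self.name!r} has duplicate members")


class GeneSetCollection(Mapping):
    """Mapping set name -> :class:`GeneSet`."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise ValidationError(f"duplicate gene set name {s.name!r}")
            self._sets[s.name] = s

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _attr(feature, line_no: int, *names: str) -> str | None:
    for name in names:
        if name in feature.attributes:
            vals = feature.attributes[name]
            if vals:
                return vals[0]
    return None


def _normalise_biotype(raw: str | None) -> str:
    if raw in ("protein_coding", "lncRNA", "spike_in"):
        return raw
    if raw in ("lincRNA", "lnc_RNA"):
        return "lncRNA"
    return "other"


def read_gtf(path) -> GeneAnnotations:
    """Read gene and exon features from a GTF v2.2 file.

    GTF 1-based inclusive coordinates become 0-based half-open; exon
    features are attached to their gene via the ``gene_id`` attribute.
    """
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    path = Path(path)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path.name}:{line_no}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                feature = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise ParseError(f"{path.name}:{line_no}: {exc}") from exc
            if feature.featuretype not in ("gene", "exon"):
                continue
            gene_id = _attr(feature, line_no, "gene_id")
            if gene_id is None:
                raise ParseError(f"{path.name}:{line_no}: missing gene_id attribute")
            start, end = feature.start - 1, feature.end  # to 0-based half-open
            if feature.featuretype == "gene":
                if gene_id in genes:
                    raise ValidationError(
                        f"{path.name}:{line_no}: duplicate gene_id {gene_id!r}"
                    )
                genes[gene_id] = dict(
                    gene_id=gene_id,
                    symbol=_attr(feature, line_no, "gene_name") or gene_id,
                    chrom=feature.seqid,
                    start=start,
                    end=end,
                    strand=feature.strand,
                    biotype=_normalise_biotype(
                        _attr(feature, line_no, "gene_biotype", "gene_type")
                    ),
                )
            else:
                exons.setdefault(gene_id, []).append((start, end))
    out = []
    for gene_id, kw in genes.items():
        kw["exons"] = tuple(exons[gene_id]) if gene_id in exons else None
        out.append(GeneAnnotation(**kw))
    return GeneAnnotations(out)


def write_gtf(annotation: GeneAnnotations, path) -> None:
    """Write genes (and their exons) back out as GTF, 1-based inclusive."""
    with open(path, "w") as fh:
        for g in annotation:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.symbol}"; '
                f'gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{g.chrom}\tlnctrace\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(g.exons or (), start=1):
                ex_attrs = f'gene_id "{g.gene_id}"; exon_number "{i}";'
                fh.write(
                    f"{g.chrom}\tlnctrace\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\t{ex_attrs}\n"
                )


# ---------------------------------------------------------------------------
# sample sheet and counts
# ---------------------------------------------------------------------------

def read_samplesheet(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SAMPLESHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"sample sheet missing columns: {missing}")
    records = [
        SampleRecord(
            sample_id=str(r.sample_id),
            genotype=str(r.genotype),
            condition=str(r.condition),
            timepoint_weeks=int(r.timepoint_weeks),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_id in sample sheet")
    return records


def write_samplesheet(samples: Sequence[SampleRecord], path) -> None:
    df = pd.DataFrame(
        [
            (s.sample_id, s.genotype, s.condition, s.timepoint_weeks, s.replicate)
            for s in samples
        ],
        columns=SAMPLESHEET_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def _read_counts_table(counts_path: Path) -> pd.DataFrame:
    if counts_path.suffix == ".mtx":
        from scipy.io import mmread

        mat = np.asarray(mmread(str(counts_path)).todense())
        rownames = Path(str(counts_path) + ".rownames").read_text().split()
        colnames = Path(str(counts_path) + ".colnames").read_text().split()
        return pd.DataFrame(mat, index=rownames, columns=colnames)
    return pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")


def read_counts(counts_path, samplesheet_path) -> CountMatrix:
    """Read counts (TSV or MTX triplet) and reorder columns to sheet order."""
    counts_path = Path(counts_path)
    samples = read_samplesheet(samplesheet_path)
    df = _read_counts_table(counts_path)
    sheet_ids = [s.sample_id for s in samples]
    extra = sorted(set(df.columns) - set(sheet_ids))
    absent = sorted(set(sheet_ids) - set(df.columns))
    if extra or absent:
        raise ReconciliationError(
            f"counts/sample-sheet mismatch: in counts only {extra}, "
            f"in sheet only {absent}"
        )
    df = df[sheet_ids]
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        frac, _ = np.modf(values.astype(float))
        if np.any(frac != 0):
            g, s = np.argwhere(frac != 0)[0]
            raise ValidationError(
                f"non-integer count at gene {df.index[g]!r}, sample {sheet_ids[s]!r}"
            )
        values = values.astype(np.int64)
    return CountMatrix([str(g) for g in df.index], samples, values)


def write_counts(cm: CountMatrix, counts_path, samplesheet_path=None) -> None:
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(counts_path), coo_matrix(cm.counts))
        Path(str(counts_path) + ".rownames").write_text("\n".join(cm.gene_ids) + "\n")
        Path(str(counts_path) + ".colnames").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        cm.to_frame().rename_axis("gene_id").to_csv(counts_path, sep="\t")
    if samplesheet_path is not None:
        write_samplesheet(cm.samples, samplesheet_path)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file; duplicate members within a set are dropped (first kept)."""
    sets = []
    path = Path(path)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name}:{line_no}: GMT line needs name, description "
                    f"and >= 1 member ({len(fields)} fields found)"
                )
            name, description = fields[0], fields[1]
            members = tuple(dict.fromkeys(m for m in fields[2:] if m))
            sets.append(GeneSet(name, description, members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            s = collection[name]
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# parameterised result tables
# ---------------------------------------------------------------------------

_PARAM_RE = re.compile(r"^#\s*(\S+?)=(.*)$")


def write_table(df: pd.DataFrame, path, params: Mapping | None = None,
                index: bool = False) -> None:
    """Write a result TSV with '# key=value' comment lines recording parameters."""
    with open(path, "w") as fh:
        for key in sorted(params or {}):
            fh.write(f"# {key}={params[key]}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def read_table(path) -> tuple[pd.DataFrame, dict[str, str]]:
    params: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            m = _PARAM_RE.match(line) if line else None
            if m:
                params[m.group(1)] = m.group(2)
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t")
    return df, params
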