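"""Readers and writers for the on-disk formats the pipeline touches.

Every reader applies the autosome filter at load time: only chromosomes
present in the :class:`~smenrich.genome.GenomeLayout` are retained, so all
downstream set algebra lives on the autosomal universe.  BED-family inputs
are 0-based half-open; GTF is 1-based inclusive and converted on read;
breakpoint tables carry 1-based positions (VCF-like convention) and are
stored 0-based internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeLayout, IntervalSet, PointSet

__all__ = [
    "SMEvent",
    "SMCallset",
    "PeakExperiment",
    "GeneAnnotation",
    "ParseError",
    "default_autosomes",
    "read_chrom_sizes",
    "read_sm_callset",
    "write_sm_callset",
    "read_peaks",
    "read_genes",
    "write_bed",
    "read_segmentation",
    "write_segmentation",
    "write_table",
    "read_manifest",
]

logger = logging.getLogger(__name__)

# Merged transcript spans (introns included, strand ignored) are a plain
# position set; keep the domain name as an alias.
GeneAnnotation = IntervalSet


class ParseError(ValueError):
    """Malformed input file."""


def default_autosomes() -> frozenset[str]:
    return frozenset(f"chr{i}" for i in range(1, 23))


@dataclass(frozen=True)
class SMEvent:
    """One structural-mutation event: two breakpoint loci (0-based)."""

    event_id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sample: str | None = None

    @property
    def interchromosomal(self) -> bool:
        return self.chrom1 != self.chrom2


@dataclass
class SMCallset:
    """A labeled collection of SM events, both breakpoints autosomal."""

    label: str
    events: list[SMEvent]
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.events)

    def breakpoints(self, layout: GenomeLayout) -> PointSet:
        pairs = []
        for ev in self.events:
            pairs.append((ev.chrom1, ev.pos1))
            pairs.append((ev.chrom2, ev.pos2))
        return PointSet.from_pairs(layout, pairs)

    def subset(self, which: str) -> "SMCallset":
        """Restrict to "all", "inter" or "intra" chromosomal events."""
        if which == "all":
            return self
        if which == "inter":
            evs = [e for e in self.events if e.interchromosomal]
        elif which == "intra":
            evs = [e for e in self.events if not e.interchromosomal]
        else:
            raise ValueError(f"unknown event subset {which!r}")
        return SMCallset(label=f"{self.label}:{which}", events=evs)


@dataclass
class PeakExperiment:
    """One ChIP-seq / DNaseI / FAIRE experiment reduced to its coverage set."""

    target: str
    cell_line: str
    lab: str
    assay_class: str  # chipseq | dnase | faire
    peaks: IntervalSet

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.target, self.cell_line, self.lab, self.assay_class)


# -- readers ----------------------------------------------------------------


def read_chrom_sizes(
    path: str | Path, autosomes: frozenset[str] | None = None
) -> GenomeLayout:
    """Two-column (name, length) table → autosome-only layout, in file order."""
    autosomes = default_autosomes() if autosomes is None else autosomes
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'name\\tlength'")
        name = parts[0]
        try:
            length = int(parts[1])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric length {parts[1]!r}") from None
        if name in seen:
            raise ParseError(f"{path}:{lineno}: duplicate chromosome {name!r}")
        seen.add(name)
        if name in autosomes:
            chroms.append((name, length))
    if not chroms:
        raise ParseError(f"{path}: no autosomal chromosomes found")
    return GenomeLayout(chroms)


_SM_COLUMNS = ("chrom1", "pos1", "chrom2", "pos2")


def read_sm_callset(path: str | Path, layout: GenomeLayout, label: str | None = None) -> SMCallset:
    """Breakpoint-pair TSV (chrom1, pos1, chrom2, pos2[, sample]); 1-based.

    Events with either breakpoint on a non-layout chromosome are dropped (the
    count is logged and kept on the callset); positions outside a layout
    chromosome's bounds are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    missing = [c for c in _SM_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    has_sample = "sample" in df.columns
    events: list[SMEvent] = []
    dropped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        bps = [(str(row.chrom1), row.pos1), (str(row.chrom2), row.pos2)]
        for chrom, pos in bps:
            if not float(pos).is_integer() or pos <= 0:
                raise ParseError(f"{path}:{lineno}: 1-based position must be ≥ 1, got {pos}")
            if chrom in layout and pos > layout.length(chrom):
                raise ParseError(
                    f"{path}:{lineno}: position {pos} beyond {chrom} length "
                    f"{layout.length(chrom)}"
                )
        if any(chrom not in layout for chrom, _ in bps):
            dropped += 1
            continue
        events.append(
            SMEvent(
                event_id=f"ev{i}",
                chrom1=bps[0][0],
                pos1=int(bps[0][1]) - 1,
                chrom2=bps[1][0],
                pos2=int(bps[1][1]) - 1,
                sample=str(row.sample) if has_sample else None,
            )
        )
    if dropped:
        logger.info("%s: dropped %d events with non-autosomal breakpoints", path, dropped)
    return SMCallset(label=label or Path(path).stem, events=events, n_dropped=dropped)


def write_sm_callset(callset: SMCallset, path: str | Path) -> None:
    rows = [
        {
            "chrom1": e.chrom1,
            "pos1": e.pos1 + 1,
            "chrom2": e.chrom2,
            "pos2": e.pos2 + 1,
            "sample": e.sample if e.sample is not None else "",
        }
        for e in callset.events
    ]
    pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2", "sample"]).to_csv(
        path, sep="\t", index=False
    )


def _read_bed_frame(path: str | Path, n_cols: int) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=range(n_cols),
        names=["chrom", "start", "end", "name"][:n_cols],
        dtype={"chrom": str},
    )
    if not (
        pd.api.types.is_integer_dtype(df["start"]) and pd.api.types.is_integer_dtype(df["end"])
    ):
        raise ParseError(f"{path}: non-integer BED coordinates")
    if (df["start"] >= df["end"]).any():
        bad = df.index[(df["start"] >= df["end"])][0] + 1
        raise ParseError(f"{path}:{bad}: start >= end")
    return df


def read_peaks(
    path: str | Path,
    layout: GenomeLayout,
    target: str,
    cell_line: str,
    lab: str,
    assay_class: str = "chipseq",
) -> PeakExperiment:
    """BED3+/narrowPeak/broadPeak → merged autosomal coverage set.

    Only the first three columns are used; records on non-layout chromosomes
    are dropped and coordinates are clipped to chromosome bounds.
    """
    df = _read_bed_frame(path, 3)
    pairs = []
    for chrom, start, end in df.itertuples(index=False):
        if chrom not in layout:
            continue
        length = layout.length(chrom)
        s, e = max(0, int(start)), min(length, int(end))
        if s < e:
            pairs.append((chrom, s, e))
    return PeakExperiment(
        target=target,
        cell_line=cell_line,
        lab=lab,
        assay_class=assay_class,
        peaks=IntervalSet.from_pairs(layout, pairs),
    )


def read_genes(path: str | Path, layout: GenomeLayout) -> GeneAnnotation:
    """GTF (transcript rows, falling back to gene rows) or BED spans.

    Returns the merged union of transcript spans on autosomes, introns
    included and strand discarded.
    """
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff", ".gff3"}:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 2, 3, 4],
            names=["chrom", "feature", "start", "end"],
            dtype={"chrom": str, "feature": str},
        )
        rows = df[df["feature"] == "transcript"]
        if rows.empty:
            rows = df[df["feature"] == "gene"]
        if rows.empty:
            raise ParseError(f"{path}: no transcript or gene rows in GTF")
        pairs = [
            (c, int(s) - 1, int(e))  # GTF is 1-based inclusive
            for c, s, e in zip(rows["chrom"], rows["start"], rows["end"])
            if c in layout
        ]
    else:
        df = _read_bed_frame(path, 3)
        pairs = [
            (c, int(s), int(e))
            for c, s, e in zip(df["chrom"], df["start"], df["end"])
            if c in layout
        ]
    pairs = [
        (c, max(0, s), min(layout.length(c), e)) for c, s, e in pairs if s < layout.length(c)
    ]
    spans = IntervalSet.from_pairs(layout, pairs)
    if spans.is_empty:
        raise ParseError(f"{path}: annotation empty after autosome filtering")
    return spans


def write_bed(iset: IntervalSet, path: str | Path, name: str | None = None) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in iset.to_pairs():
            if name is None:
                fh.write(f"{chrom}\t{s}\t{e}\n")
            else:
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


# -- tabular results --------------------------------------------------------


def write_table(records: Sequence, path: str | Path, sort_by: Sequence[str] | None = None) -> None:
    """Write homogeneous dataclass records as a TSV with a stable row order.

    Floats are rendered at 6 significant digits; an empty record list yields
    a header-only file when the record type is known (pass a list with a
    ``columns`` attribute or a non-empty list).
    """
    if len(records) == 0:
        Path(path).write_text("")
        return
    first = records[0]
    cols = [f.name for f in dc_fields(first)]
    rows = [{c: getattr(r, c) for c in cols} for r in records]
    df = pd.DataFrame(rows, columns=cols)
    if sort_by:
        df = df.sort_values(list(sort_by), kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_segmentation(path: str | Path, layout: GenomeLayout, cell_line: str = "", lab: str = ""):
    """BED4 chromatin-state segmentation → :class:`~smenrich.chromstate.StateSegmentation`.

    Blocks are clipped to the layout, must not overlap within a chromosome,
    and the state catalog is the distinct labels in order of first appearance.
    """
    from .chromstate import StateSegmentation  # deferred: chromstate uses io types

    df = _read_bed_frame(path, 4)
    catalog: list[str] = []
    code_of: dict[str, int] = {}
    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    codes: dict[str, list[int]] = {}
    for chrom, start, end, name in df.itertuples(index=False):
        if chrom not in layout:
            continue
        label = str(name)
        if label not in code_of:
            code_of[label] = len(catalog)
            catalog.append(label)
        s, e = max(0, int(start)), min(layout.length(chrom), int(end))
        if s < e:
            starts.setdefault(chrom, []).append(s)
            ends.setdefault(chrom, []).append(e)
            codes.setdefault(chrom, []).append(code_of[label])
    seg_starts, seg_ends, seg_codes = {}, {}, {}
    for chrom in starts:
        s = np.asarray(starts[chrom], dtype=np.int64)
        e = np.asarray(ends[chrom], dtype=np.int64)
        c = np.asarray(codes[chrom], dtype=np.int64)
        order = np.argsort(s, kind="stable")
        s, e, c = s[order], e[order], c[order]
        if (s[1:] < e[:-1]).any():
            i = int(np.flatnonzero(s[1:] < e[:-1])[0])
            raise ParseError(
                f"{path}: overlapping blocks on {chrom} near position {int(s[i + 1])}"
            )
        seg_starts[chrom], seg_ends[chrom], seg_codes[chrom] = s, e, c
    return StateSegmentation(
        layout=layout,
        catalog=catalog,
        starts=seg_starts,
        ends=seg_ends,
        codes=seg_codes,
        cell_line=cell_line,
        lab=lab,
    )


def write_segmentation(seg, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in seg.layout.names:
            if chrom not in seg.starts:
                continue
            for s, e, c in zip(seg.starts[chrom], seg.ends[chrom], seg.codes[chrom]):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{seg.catalog[int(c)]}\n")


@dataclass
class ManifestEntry:
    target: str
    cell_line: str
    lab: str
    assay_class: str
    path: str


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """TSV manifest of peak experiments: target, cell_line, lab, assay_class, path."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["target", "cell_line", "lab", "assay_class", "path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: manifest missing columns {missing}")
    base = Path(path).parent
    entries = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        entries.append(
            ManifestEntry(row.target, row.cell_line, row.lab, row.assay_class, str(p))
        )
    return entries
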