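"""Gene models and 3'UTR quantification features.

Two feature sets drive the localization analysis:

* one *union 3'UTR* per gene (the union of all annotated 3'UTR intervals of
  its transcripts), used for gene-level quantification; and
* per-gene *3'-isoform terminal windows*: the last ``window`` (default 500)
  nt of transcript sequence upstream of each distinct annotated 3' end,
  with ends closer than ``merge_dist`` merged into a single feature and any
  residual overlap between features of one gene resolved by truncating the
  more 5' feature.  These windows are the isoform quantification features.

Coordinates are 0-based half-open genomic intervals throughout; GTF input is
converted on read.  "Upstream" and "5' -> 3'" refer to transcript
orientation, i.e. genomically reversed on the minus strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

log = logging.getLogger(__name__)

Interval = tuple[int, int]

ALE = "ALE"
TANDEM = "tandem"


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    utr3_intervals: tuple[Interval, ...]  # sorted, non-overlapping, genomic
    end3: int  # genomic position of the 3' terminus (half-open convention)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")


@dataclass(frozen=True)
class UtrFeature:
    feature_id: str
    gene_id: str
    chrom: str
    strand: str
    intervals: tuple[Interval, ...]
    kind: str  # "union_utr" | "isoform_window"
    member_end3s: tuple[int, ...] = ()

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]


@dataclass(frozen=True)
class IsoformPairClass:
    gene_id: str
    proximal_feature_id: str
    distal_feature_id: str
    cls: str  # ALE | tandem


# ---------------------------------------------------------------------------
# interval arithmetic

def merge_intervals(intervals) -> tuple[Interval, ...]:
    """Union of half-open intervals; abutting intervals are joined."""
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty/inverted interval ({s},{e})")
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return tuple((s, e) for s, e in out)


def _clip_intervals(intervals, lo=None, hi=None) -> tuple[Interval, ...]:
    out = []
    for s, e in intervals:
        if lo is not None:
            s = max(s, lo)
        if hi is not None:
            e = min(e, hi)
        if s < e:
            out.append((s, e))
    return tuple(out)


def transcript_end3(intervals, strand: str) -> int:
    if strand == "+":
        return max(e for _, e in intervals)
    return min(s for s, _ in intervals)


# ---------------------------------------------------------------------------
# loading

def load_gene_models(path, fmt: str | None = None) -> list[GeneModel]:
    """Parse gene annotations into :class:`GeneModel` objects.

    ``fmt`` is one of ``"gtf"``/``"gff3"``/``"bed12"``; inferred from the
    file extension when omitted.  Transcripts lacking a 3'UTR are dropped
    with a logged warning; a gene whose transcripts disagree on chrom or
    strand raises ``ValueError``.
    """
    path = str(path)
    if fmt is None:
        low = path.lower()
        if low.endswith((".bed", ".bed12")):
            fmt = "bed12"
        elif low.endswith((".gff", ".gff3")):
            fmt = "gff3"
        else:
            fmt = "gtf"
    if fmt == "bed12":
        raw = _read_bed12(path)
    elif fmt in ("gtf", "gff3"):
        raw = _read_gxf(path, fmt)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return _assemble(raw)


def _assemble(records) -> list[GeneModel]:
    """records: iterable of (gene_id, transcript_id, chrom, strand, intervals)."""
    genes: dict[str, GeneModel] = {}
    for gene_id, tx_id, chrom, strand, intervals in records:
        if not intervals:
            log.warning("transcript %s has no 3'UTR; dropped", tx_id)
            continue
        intervals = merge_intervals(intervals)
        g = genes.get(gene_id)
        if g is None:
            g = genes[gene_id] = GeneModel(gene_id, chrom, strand)
        elif g.chrom != chrom or g.strand != strand:
            raise ValueError(
                f"gene {gene_id}: transcripts on mixed chrom/strand "
                f"({g.chrom}{g.strand} vs {chrom}{strand})"
            )
        g.transcripts.append(
            Transcript(tx_id, intervals, transcript_end3(intervals, strand))
        )
    return [genes[k] for k in sorted(genes)]


_UTR3_TYPES = {"three_prime_utr", "three_prime_UTR", "3UTR"}


def _read_gxf(path, fmt):
    import gffutils

    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # unparseable input
        raise ValueError(f"could not parse {path} as {fmt}: {exc}") from exc

    def _attr(f, key):
        v = f.attributes.get(key)
        return v[0] if v else None

    out = []
    for ftype in _UTR3_TYPES:
        for f in db.features_of_type(ftype):
            tx = _attr(f, "transcript_id")
            gene = _attr(f, "gene_id")
            if tx is None:  # GFF3 dialect: resolve via Parent
                parent = _attr(f, "Parent")
                if parent:
                    tx = parent.split(":")[-1]
            if gene is None and tx is not None:
                for p in db.parents(f, level=None):
                    gid = _attr(p, "gene_id")
                    if gid:
                        gene = gid
                        break
            if tx is None or gene is None:
                log.warning("UTR record without gene/transcript id skipped: %s", f)
                continue
            # GTF/GFF are 1-based closed; convert to 0-based half-open
            out.append((gene, tx, (f.start - 1, f.end), f.seqid, f.strand))
    grouped: dict[tuple, list] = {}
    for gene, tx, iv, chrom, strand in out:
        grouped.setdefault((gene, tx, chrom, strand), []).append(iv)
    return [
        (gene, tx, chrom, strand, ivs)
        for (gene, tx, chrom, strand), ivs in grouped.items()
    ]


def _read_bed12(path):
    """BED12 transcripts; 3'UTR = thin region 3' of the CDS within blocks.

    The name column encodes ``gene_id|transcript_id`` (a bare name is used as
    both).  Non-coding entries (thickStart == thickEnd) have no 3'UTR and
    are dropped by the assembler.
    """
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{ln}: BED12 requires 12 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5]
            thick_s, thick_e = int(parts[6]), int(parts[7])
            nblocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offs = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != nblocks or len(offs) != nblocks:
                raise ValueError(f"{path}:{ln}: block count mismatch")
            blocks = [(start + o, start + o + sz) for o, sz in zip(offs, sizes)]
            if "|" in name:
                gene, tx = name.split("|", 1)
            else:
                gene = tx = name
            if thick_s >= thick_e:  # non-coding: no annotated CDS
                utr = []
            elif strand == "+":
                utr = _clip_intervals(blocks, lo=thick_e)
            else:
                utr = _clip_intervals(blocks, hi=thick_s)
            records.append((gene, tx, chrom, strand, list(utr)))
    return records


# ---------------------------------------------------------------------------
# feature construction

def build_union_utr(g: GeneModel) -> UtrFeature:
    """Union of all 3'UTR intervals of a gene's transcripts."""
    if not g.transcripts:
        raise ValueError(f"gene {g.gene_id} has no transcripts with a 3'UTR")
    ivs = merge_intervals(
        [iv for t in g.transcripts for iv in t.utr3_intervals]
    )
    ends = tuple(sorted({t.end3 for t in g.transcripts}))
    return UtrFeature(
        f"{g.gene_id}:utr", g.gene_id, g.chrom, g.strand, ivs, "union_utr", ends
    )


def _terminal_window(t: Transcript, strand: str, window: int) -> tuple[Interval, ...]:
    """Last ``window`` nt of a transcript's 3'UTR, in transcript space.

    Walks the UTR exon intervals from the 3' terminus upstream, so windows
    crossing splice junctions stay 500 nt of *transcript* sequence.
    """
    remaining = window
    out = []
    ivs = t.utr3_intervals
    order = reversed(ivs) if strand == "+" else ivs
    for s, e in order:
        if remaining <= 0:
            break
        take = min(remaining, e - s)
        if strand == "+":
            out.append((e - take, e))
        else:
            out.append((s, s + take))
        remaining -= take
    return merge_intervals(out)


def _transcript_space_positions(g: GeneModel, ends):
    """Map genomic end positions onto a cumulative coordinate along the
    union 3'UTR (used for transcript-space end-to-end distances)."""
    union = merge_intervals([iv for t in g.transcripts for iv in t.utr3_intervals])
    pos = {}
    for e3 in ends:
        cum = 0
        for s, e in union:
            anchor = e3 if g.strand == "+" else e3 + 1
            if anchor <= e:
                cum += max(0, anchor - s)
                break
            cum += e - s
        pos[e3] = cum
    return pos


def build_isoform_windows(
    g: GeneModel,
    window: int = 500,
    merge_dist: int = 500,
    coord_space: str = "genomic",
) -> list[UtrFeature]:
    """Non-overlapping terminal-window features, one per (merged) 3' end.

    Distinct transcript 3'-end positions closer than ``merge_dist`` are
    merged into a single feature (single-linkage along the strand);
    the feature is the union of the member ends' individual ``window``-nt
    terminal windows.  Residual overlap between adjacent features of the
    same gene is resolved by truncating the more 5' feature at the more 3'
    feature's start.  Output is ordered 5' -> 3' in transcript orientation.
    """
    if window <= 0 or merge_dist <= 0:
        raise ValueError("window and merge_dist must be positive")
    if coord_space not in ("genomic", "transcript"):
        raise ValueError(f"unknown coord_space {coord_space!r}")

    by_end: dict[int, list[Transcript]] = {}
    for t in g.transcripts:
        by_end.setdefault(t.end3, []).append(t)
    # 5' -> 3' in transcript orientation
    ends = sorted(by_end, reverse=(g.strand == "-"))
    if not ends:
        return []

    if coord_space == "transcript":
        coord = _transcript_space_positions(g, ends)
        dist = lambda a, b: abs(coord[a] - coord[b])
    else:
        dist = lambda a, b: abs(a - b)

    clusters: list[list[int]] = [[ends[0]]]
    for e3 in ends[1:]:
        if dist(clusters[-1][-1], e3) < merge_dist:
            clusters[-1].append(e3)
        else:
            clusters.append([e3])

    feats = []
    for k, members in enumerate(clusters, start=1):
        wins = []
        for e3 in members:
            for t in by_end[e3]:
                wins.extend(_terminal_window(t, g.strand, window))
        feats.append(
            UtrFeature(
                f"{g.gene_id}:iso{k}",
                g.gene_id,
                g.chrom,
                g.strand,
                merge_intervals(wins),
                "isoform_window",
                tuple(sorted(members)),
            )
        )

    # truncate each upstream feature at the next (more 3') feature's start
    out = []
    for i, f in enumerate(feats):
        ivs = f.intervals
        if i + 1 < len(feats):
            nxt = feats[i + 1]
            if g.strand == "+":
                ivs = _clip_intervals(ivs, hi=min(s for s, _ in nxt.intervals))
            else:
                ivs = _clip_intervals(ivs, lo=max(e for _, e in nxt.intervals))
        if ivs:
            out.append(replace(f, intervals=ivs))
        else:
            log.warning(
                "feature %s removed: fully shadowed by a more 3' feature", f.feature_id
            )
    return out


def classify_pair(proximal_utr, distal_utr) -> str:
    """ALE vs tandem from full-length 3'UTR geometry.

    ``tandem`` iff the two full-length UTR interval sets overlap or directly
    abut (gap 0); ``ALE`` otherwise.
    """
    a = merge_intervals(proximal_utr)
    b = merge_intervals(distal_utr)
    for s1, e1 in a:
        for s2, e2 in b:
            if s1 <= e2 and s2 <= e1:  # half-open: equality means abutting
                return TANDEM
    return ALE


def classify_gene_pair(
    g: GeneModel, proximal: UtrFeature, distal: UtrFeature
) -> IsoformPairClass:
    """Classify a proximal/distal feature pair using the full-length UTRs of
    the transcripts whose 3' ends belong to each feature."""

    def _full(feature):
        ivs = []
        for t in g.transcripts:
            if t.end3 in feature.member_end3s:
                ivs.extend(t.utr3_intervals)
        return ivs

    cls = classify_pair(_full(proximal), _full(distal))
    return IsoformPairClass(g.gene_id, proximal.feature_id, distal.feature_id, cls)


# ---------------------------------------------------------------------------
# output

def gene_models_to_bed12(genes, path) -> None:
    """Write gene models as BED12 transcripts whose blocks are the 3'UTRs.

    A one-base thick (CDS) region is placed at the transcript start so the
    remainder of the blocks round-trips as the 3'UTR through
    :func:`load_gene_models`; names encode ``gene_id|transcript_id``.
    """
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: g.gene_id):
            for t in g.transcripts:
                ivs = t.utr3_intervals
                start, end = ivs[0][0], ivs[-1][1]
                if g.strand == "+":
                    thick_s, thick_e = start, start + 1
                else:
                    thick_s, thick_e = end - 1, end
                sizes = ",".join(str(e - s) for s, e in ivs) + ","
                offs = ",".join(str(s - start) for s, _ in ivs) + ","
                fh.write(
                    f"{g.chrom}\t{start}\t{end}\t{g.gene_id}|{t.transcript_id}"
                    f"\t0\t{g.strand}\t{thick_s}\t{thick_e}\t0\t{len(ivs)}"
                    f"\t{sizes}\t{offs}\n"
                )


def features_to_bed6(features, path) -> None:
    with open(path, "w") as fh:
        for f in features:
            for s, e in f.intervals:
                fh.write(f"{f.chrom}\t{s}\t{e}\t{f.feature_id}\t0\t{f.strand}\n")


def features_to_table(features):
    import pandas as pd

    return pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in features],
            "gene_id": [f.gene_id for f in features],
            "chrom": [f.chrom for f in features],
            "strand": [f.strand for f in features],
            "kind": [f.kind for f in features],
            "intervals": [
                ";".join(f"{s}-{e}" for s, e in f.intervals) for f in features
            ],
            "length": [f.length for f in features],
            "member_end3s": [
                ";".join(map(str, f.member_end3s)) for f in features
            ],
        }
    )
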