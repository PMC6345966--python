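"""Novel miRNA candidate discovery and hairpin duplex validation.

Clean unassigned tags with sufficient abundance seed candidate loci; a
flanked genomic window is folded (by an injected MFE engine) and the
resulting duplex geometry is screened against three structural criteria:

1. the mature and its star come from opposite stem arms and form a duplex
   with 2-nt 3' overhangs;
2. pairing within the duplex is extensive (at most four mature positions
   unpaired or paired outside the star);
3. at most one asymmetric bulge, no larger than 2 nt, inside the duplex.

The folding engine is a plain callable ``seq -> (dot_bracket, mfe)`` so
tests can inject deterministic structures; production wiring uses the
ViennaRNA minimum-free-energy folder when available.
"""

from __future__ import annotations

import logging
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from ._seq import revcomp, to_rna
from .preprocess import TagTable

log = logging.getLogger(__name__)

FoldEngine = Callable[[str], tuple[str, float]]

DEFAULT_MIN_ABUNDANCE = 10
DEFAULT_FLANK = 100
MAX_LOCI = 20
OVERHANG = 2

REASON_FOLD = "fold_error"
REASON_NO_DUPLEX = "no_duplex"
REASON_ARMS = "opposite_arms"
REASON_MISMATCH = "mismatches>4"
REASON_BULGE_COUNT = "bulges>1"
REASON_BULGE_SIZE = "bulge>2nt"

ORIGIN_EXONIC = "exonic"
ORIGIN_INTRONIC = "intronic"
ORIGIN_INTERGENIC = "intergenic"


@dataclass
class CandidateLocus:
    chrom: str
    start: int  # of the mature tag, 0-based half-open on the + strand
    end: int
    strand: str
    mature_tag: str  # oriented along the strand
    count: int
    window_start: int
    window_seq: str  # oriented along the strand
    mature_span: tuple[int, int]  # on window_seq


@dataclass
class DuplexGeometry:
    n_mismatch: int
    bulges: list[tuple[str, int]] = field(default_factory=list)  # (arm, size)


@dataclass
class HairpinCandidate:
    locus: CandidateLocus
    precursor_seq: str
    structure: str | None = None
    mfe: float | None = None
    star_span: tuple[int, int] | None = None
    geometry: DuplexGeometry | None = None
    verdict: bool = False
    failure_reasons: list[str] = field(default_factory=list)
    origin: str | None = None


def candidate_loci(
    tags: TagTable,
    genome: dict[str, str],
    min_abundance: int = DEFAULT_MIN_ABUNDANCE,
    flank: int = DEFAULT_FLANK,
    max_loci: int = MAX_LOCI,
) -> list[CandidateLocus]:
    """Group genome-mapped tags into candidate loci.

    Overlapping tag placements on one strand are merged into one locus led
    by the most abundant tag; a locus is emitted when its lead tag's summed
    count reaches *min_abundance*.  Tags hitting more than *max_loci*
    genomic positions are treated as repeat-derived and dropped.
    """
    placements: list[tuple[str, str, int, int, str, int]] = []
    for tag, counts in tags.counts.items():
        total = sum(counts.values())
        if total <= 0:
            continue
        hits = []
        rc = revcomp(tag)
        for chrom, seq in genome.items():
            for needle, strand in ((tag, "+"), (rc, "-")):
                i = seq.find(needle)
                while i != -1:
                    hits.append((chrom, strand, i, i + len(tag)))
                    i = seq.find(needle, i + 1)
        if len(hits) > max_loci:
            log.info("tag with %d genomic loci discarded as repeat-derived", len(hits))
            continue
        for chrom, strand, s, e in hits:
            placements.append((chrom, strand, s, e, tag, total))

    placements.sort(key=lambda p: (p[0], p[1], p[2], p[3]))
    loci: list[CandidateLocus] = []
    cluster: list[tuple[str, str, int, int, str, int]] = []

    def flush() -> None:
        if not cluster:
            return
        lead = max(cluster, key=lambda p: (p[5], -p[2]))
        chrom, strand, s, e, tag, total = lead
        if total < min_abundance:
            return
        seq = genome[chrom]
        ws, we = max(0, s - flank), min(len(seq), e + flank)
        window = seq[ws:we]
        if strand == "+":
            span = (s - ws, e - ws)
        else:
            window = revcomp(window)
            span = (we - e, we - s)
            tag = revcomp(tag)
        loci.append(
            CandidateLocus(
                chrom=chrom,
                start=s,
                end=e,
                strand=strand,
                mature_tag=tag,
                count=total,
                window_start=ws,
                window_seq=window,
                mature_span=span,
            )
        )

    prev = None
    for p in placements:
        if prev is not None and (p[0] != prev[0] or p[1] != prev[1] or p[2] >= max(c[3] for c in cluster)):
            flush()
            cluster = []
        cluster.append(p)
        prev = p
    flush()
    return loci


def viennarna_engine(seq: str) -> tuple[str, float]:
    """MFE folding via ViennaRNA (python bindings, else the RNAfold binary)."""
    rna = to_rna(seq)
    try:
        import RNA  # type: ignore

        structure, mfe = RNA.fold(rna)
        return structure, float(mfe)
    except ImportError:
        pass
    proc = subprocess.run(
        ["RNAfold", "--noPS"], input=rna + "\n", capture_output=True, text=True, check=True
    )
    lines = proc.stdout.strip().splitlines()
    structure, _, energy = lines[-1].partition(" ")
    return structure.strip(), float(energy.strip().strip("()"))


def make_stub_engine(table: dict[str, tuple[str, float]]) -> FoldEngine:
    """Deterministic folding stub returning pre-computed structures."""

    def engine(seq: str) -> tuple[str, float]:
        return table[seq]

    return engine


def fold(precursor_seq: str, engine: FoldEngine) -> tuple[str, float]:
    """Run the injected folder and validate its output contract."""
    try:
        structure, mfe = engine(precursor_seq)
    except Exception as exc:  # engine failure rejects the candidate
        raise FoldError(str(exc)) from exc
    if len(structure) != len(precursor_seq):
        raise FoldError("structure length differs from sequence length")
    depth = 0
    for c in structure:
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise FoldError("unbalanced dot-bracket structure")
        elif c != ".":
            raise FoldError(f"invalid structure character {c!r}")
    if depth != 0:
        raise FoldError("unbalanced dot-bracket structure")
    return structure, float(mfe)


class FoldError(RuntimeError):
    pass


def pair_table(structure: str) -> list[int | None]:
    """Partner index per position (None = unpaired) from dot-bracket text."""
    partner: list[int | None] = [None] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            partner[i], partner[j] = j, i
    return partner


def validate_hairpin(
    precursor_seq: str,
    structure: str,
    mature_span: tuple[int, int],
    overhang: int = OVERHANG,
) -> tuple[bool, list[str], DuplexGeometry, tuple[int, int] | None]:
    """Screen a folded precursor against the three duplex criteria.

    The star span is derived from the base-pairing partners of the mature
    positions shifted by the canonical 2-nt 3' overhang (minimal covering
    interval when partners are discontinuous).  Returns (verdict, failure
    reasons, duplex geometry, star span).
    """
    ms, me = mature_span
    if not (0 <= ms < me <= len(structure)) or len(structure) != len(precursor_seq):
        raise ValueError("mature span not covered by the structure")
    partner = pair_table(structure)
    reasons: list[str] = []

    partners = [(i, partner[i]) for i in range(ms, me) if partner[i] is not None]
    if not partners:
        return False, [REASON_NO_DUPLEX], DuplexGeometry(n_mismatch=me - ms), None

    # a mature pairing with itself spans the terminal loop: not a duplex
    if any(ms <= q < me for _, q in partners):
        return False, [REASON_ARMS], DuplexGeometry(n_mismatch=0), None

    qs = [q for _, q in partners]
    lo, hi = min(qs), max(qs)
    if not (lo >= me or hi < ms):
        return False, [REASON_ARMS], DuplexGeometry(n_mismatch=0), None
    # the +2 offset points toward the star's 3' end on either arm: the
    # star's 3' terminus overhangs the mature 5' end by two nucleotides
    star = (lo + overhang, hi + 1 + overhang)
    star = (max(star[0], 0), min(star[1], len(precursor_seq)))
    if star[0] < me and ms < star[1]:
        return False, [REASON_ARMS], DuplexGeometry(n_mismatch=0), star

    # duplex region of the mature excludes its own 2-nt 3' overhang
    dms, dme = ms, me - overhang
    n_mismatch = sum(
        1
        for i in range(dms, dme)
        if partner[i] is None or not (star[0] <= partner[i] < star[1])
    )
    if n_mismatch > 4:
        reasons.append(REASON_MISMATCH)

    duplex_pairs = [
        (i, partner[i])
        for i in range(dms, dme)
        if partner[i] is not None and star[0] <= partner[i] < star[1]
    ]
    bulges: list[tuple[str, int]] = []
    for (i1, q1), (i2, q2) in zip(duplex_pairs, duplex_pairs[1:]):
        gap_m = i2 - i1 - 1
        gap_s = abs(q1 - q2) - 1
        if gap_m != gap_s:
            size = abs(gap_m - gap_s)
            bulges.append(("mature" if gap_m > gap_s else "star", size))
    if len(bulges) > 1:
        reasons.append(REASON_BULGE_COUNT)
    if any(size > 2 for _, size in bulges):
        reasons.append(REASON_BULGE_SIZE)

    geometry = DuplexGeometry(n_mismatch=n_mismatch, bulges=bulges)
    return not reasons, reasons, geometry, star


def annotate_origin(
    locus: tuple[str, int, int],
    gene_models,
) -> str:
    """Label a locus exonic / intronic / intergenic against gene models.

    *gene_models* is a gffutils FeatureDB (or anything whose ``region``
    method yields features with 1-based inclusive ``start``/``end``).  Any
    exon overlap wins; otherwise overlap with a gene body is intronic.
    """
    chrom, start, end = locus
    overlapping = list(gene_models.region(region=(chrom, start + 1, end), completely_within=False))
    has_gene = False
    for f in overlapping:
        f_start, f_end = f.start - 1, f.end  # to 0-based half-open
        if f_start < end and start < f_end:
            if f.featuretype == "exon":
                return ORIGIN_EXONIC
            if f.featuretype == "gene":
                has_gene = True
    return ORIGIN_INTRONIC if has_gene else ORIGIN_INTERGENIC


def load_gene_models(gff3_path: str | Path):
    import gffutils

    return gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def discover_novel(
    tags: TagTable,
    genome: dict[str, str],
    engine: FoldEngine,
    gene_models=None,
    min_abundance: int = DEFAULT_MIN_ABUNDANCE,
    flank: int = DEFAULT_FLANK,
) -> list[HairpinCandidate]:
    """End-to-end novel-miRNA screen on clean unassigned tags."""
    out: list[HairpinCandidate] = []
    for locus in candidate_loci(tags, genome, min_abundance=min_abundance, flank=flank):
        cand = HairpinCandidate(locus=locus, precursor_seq=locus.window_seq)
        try:
            structure, mfe = fold(locus.window_seq, engine)
        except FoldError as exc:
            cand.failure_reasons = [REASON_FOLD]
            log.warning("fold failed for locus %s:%d-%d: %s", locus.chrom, locus.start, locus.end, exc)
            out.append(cand)
            continue
        cand.structure, cand.mfe = structure, mfe
        verdict, reasons, geometry, star = validate_hairpin(
            locus.window_seq, structure, locus.mature_span
        )
        cand.verdict, cand.failure_reasons, cand.geometry, cand.star_span = (
            verdict,
            reasons,
            geometry,
            star,
        )
        if gene_models is not None:
            cand.origin = annotate_origin((locus.chrom, locus.start, locus.end), gene_models)
        out.append(cand)
    return out
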