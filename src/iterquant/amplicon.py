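"""Amplicon-sequencing quantification of base-editing outcomes.

Given single (pre-merged) amplicon reads, this module demultiplexes by 6-nt
inline index, filters on mean read quality, aligns each read to its amplicon
semi-globally, and scores editing inside a quantification window on the
protospacer: per-position substitution percentages, an indel class, an allele
spectrum, and a zygosity call for regenerated plants.

Position numbering is 1-based 5'->3' along the protospacer for both nuclease
classes.  Because Cas9's PAM sits 3' of the protospacer and Cas12a's sits 5',
this single convention corresponds to "PAM-distal base is position 1" for
Cas9 guides and "PAM-adjacent base is position 1" for Cas12a guides; the
convention tag on each table records which label applies.

Default quantification parameters: window size 10, window center -12 relative
to the protospacer 3' end, cleavage offset -1 for substitution bookkeeping,
cleavage offset -4 (Cas12a) for the indel window, and a minimum mean read
quality of Q30.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from .errors import ConfigurationError, FormatError, InputError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return str(reverse_complement(seq))


# ---------------------------------------------------------------------------
# targets and windows
# ---------------------------------------------------------------------------


@dataclass
class AmpliconTarget:
    """An amplicon with its protospacer and quantification parameters.

    The protospacer must occur exactly once in the amplicon on the stated
    strand.  ``strand='+'`` means the protospacer reads 5'->3' on the amplicon
    top strand; ``'-'`` means its reverse complement occurs in the amplicon.
    """

    target_id: str
    amplicon: str
    protospacer: str
    strand: str = "+"
    nuclease: str = "Cas12a"
    window_size: int = 10
    window_center: int = -12
    cleavage_offset: int = -1
    indel_offset: int = -4
    min_mean_quality: float = 30.0

    def __post_init__(self) -> None:
        self.amplicon = self.amplicon.upper()
        self.protospacer = self.protospacer.upper()
        if self.strand not in "+-":
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.window_size < 1:
            raise ConfigurationError("window size must be >= 1")
        if self.min_mean_quality < 0:
            raise ConfigurationError("minimum quality must be >= 0")
        query = self.protospacer if self.strand == "+" else _revcomp(self.protospacer)
        n = self.amplicon.count(query)
        if n != 1:
            raise ConfigurationError(
                f"protospacer must occur exactly once on strand {self.strand} "
                f"of amplicon {self.target_id!r} (found {n})"
            )
        self._match_start = self.amplicon.index(query)

    @property
    def spacer_length(self) -> int:
        return len(self.protospacer)

    def proto_to_amplicon(self, pos: int) -> int:
        """1-based protospacer position -> 0-based amplicon coordinate."""
        if not 1 <= pos <= self.spacer_length:
            raise InputError(f"protospacer position {pos} outside 1..{self.spacer_length}")
        if self.strand == "+":
            return self._match_start + pos - 1
        return self._match_start + self.spacer_length - pos

    def read_base_to_proto(self, base: str) -> str:
        """Orient an amplicon-top-strand base into protospacer sense."""
        return base if self.strand == "+" else base.translate(_COMPLEMENT)

    @property
    def numbering_convention(self) -> str:
        if self.nuclease.lower() == "cas9":
            return "5'->3' of protospacer (PAM-distal base is position 1)"
        return "5'->3' of protospacer (PAM-adjacent base is position 1)"


def _centered_window(length: int, width: int, center: int) -> list[int]:
    lo = center - math.ceil(width / 2) + 1
    hi = center + math.floor(width / 2)
    return [p for p in range(max(1, lo), min(length, hi) + 1)]


def quantification_window(target: AmpliconTarget) -> list[int]:
    """Protospacer positions scored for substitutions.

    The window of size w is centered at position L + c (L = spacer length,
    c = window center, a negative offset from the 3' end), spanning
    [center - ceil(w/2) + 1, center + floor(w/2)] clipped to [1, L].
    For L=20, w=10, c=-12 this is the canonical base-editing window 4-13.
    """
    L = target.spacer_length
    if abs(target.window_center) >= L:
        raise ConfigurationError("window center outside the protospacer")
    window = _centered_window(L, target.window_size, L + target.window_center)
    if not window:
        raise ConfigurationError("quantification window is empty after clipping")
    return window


def indel_window(target: AmpliconTarget) -> list[int]:
    """Protospacer positions of the indel window, centered at the cleavage
    position L + indel_offset with the same size/clipping rule."""
    L = target.spacer_length
    window = _centered_window(L, target.window_size, L + target.indel_offset)
    if not window:
        raise ConfigurationError("indel window is empty after clipping")
    return window


# ---------------------------------------------------------------------------
# demultiplexing and quality filtering
# ---------------------------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads, index_table: dict[str, str], max_mismatch: int = 0
) -> tuple[dict[str, list], list, pd.DataFrame]:
    """Assign reads to samples by their 5' 6-nt inline index.

    A read is assigned when exactly one sample index lies within
    ``max_mismatch`` of its prefix; the index bases are trimmed from assigned
    reads.  Returns (per-sample reads, unassigned reads, statistics table).
    Indices must be 6 nt and pairwise separated by more than 2*max_mismatch
    so no prefix can match two samples.
    """
    samples = list(index_table)
    for sample, idx in index_table.items():
        if len(idx) != 6:
            raise ConfigurationError(f"index for {sample!r} is not 6 nt: {idx!r}")
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            if _hamming(index_table[a], index_table[b]) <= 2 * max_mismatch:
                raise ConfigurationError(
                    f"index collision between {a!r} and {b!r} at max_mismatch={max_mismatch}"
                )
    assigned: dict[str, list] = {s: [] for s in samples}
    unassigned = []
    for read in reads:
        prefix = read.seq[:6].upper()
        hits = [s for s in samples if _hamming(prefix, index_table[s]) <= max_mismatch]
        if len(hits) == 1:
            trimmed = read._replace(seq=read.seq[6:], qual=read.qual[6:])
            assigned[hits[0]].append(trimmed)
        else:
            unassigned.append(read)
    stats = pd.DataFrame(
        {
            "sample": samples + ["unassigned"],
            "index": [index_table[s] for s in samples] + [""],
            "n_reads": [len(assigned[s]) for s in samples] + [len(unassigned)],
        }
    )
    return assigned, unassigned, stats


def mean_quality(qual: str) -> float:
    """Mean Phred score of a Phred+33 quality string."""
    if not qual:
        raise FormatError("empty quality string")
    scores = [ord(c) - 33 for c in qual]
    if any(q < 0 or q > 93 for q in scores):
        raise FormatError(f"quality string contains non-Phred+33 characters: {qual!r}")
    return sum(scores) / len(scores)


def quality_filter(reads, min_quality: float = 30.0) -> tuple[list, list]:
    """Split reads into (passing, failing) on mean Phred >= min_quality."""
    passing, failing = [], []
    for read in reads:
        if len(read.seq) != len(read.qual):
            raise FormatError(
                f"record {read.id!r}: sequence and quality lengths differ"
            )
        (passing if mean_quality(read.qual) >= min_quality else failing).append(read)
    return passing, failing


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignedRead:
    """A read placed on amplicon coordinates.

    ``bases`` maps 0-based amplicon coordinate -> read base (top strand);
    ``indels`` lists (kind, amplicon position, length, inserted sequence)
    where a deletion spans [pos, pos+length) and an insertion sits at the
    junction immediately before ``pos``.
    """

    read_id: str
    orientation: str  # '+' or '-'
    span: tuple[int, int]  # [start, end) amplicon coords covered
    bases: dict[int, str]
    indels: list[tuple[str, int, int, str]]
    score: float

    @property
    def has_indel(self) -> bool:
        return bool(self.indels)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    # free end gaps on the amplicon (semi-global: the read may land anywhere)
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def _parse_alignment(aln, read_seq: str) -> tuple[dict[int, str], list, tuple[int, int]]:
    t_blocks, q_blocks = aln.aligned
    bases: dict[int, str] = {}
    indels: list[tuple[str, int, int, str]] = []
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for k in range(te - ts):
            bases[ts + k] = read_seq[qs + k]
    for i in range(len(t_blocks) - 1):
        dt = int(t_blocks[i + 1][0] - t_blocks[i][1])
        dq = int(q_blocks[i + 1][0] - q_blocks[i][1])
        if dt > 0:
            indels.append(("del", int(t_blocks[i][1]), dt, ""))
        if dq > 0:
            ins_seq = read_seq[int(q_blocks[i][1]) : int(q_blocks[i + 1][0])]
            indels.append(("ins", int(t_blocks[i + 1][0]), dq, ins_seq))
    span = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    return bases, indels, span


def align_read(read, target: AmpliconTarget) -> AlignedRead | None:
    """Semi-global alignment of one read to the amplicon.

    Both orientations are scored (match +2, mismatch -1, gap open -5, gap
    extend -1; free end gaps on the amplicon); the higher-scoring one wins.
    Returns None when the best score falls below 0.4 * 2 * read length
    (unalignable read).
    """
    seq = read.seq.upper()
    if len(seq) < 30:
        raise InputError(f"read {read.id!r} shorter than 30 nt")
    best = None
    for orientation, s in (("+", seq), ("-", _revcomp(seq))):
        aln = _ALIGNER.align(target.amplicon, s)[0]
        if best is None or aln.score > best[0]:
            best = (aln.score, orientation, aln, s)
    score, orientation, aln, oriented = best
    if score < 0.4 * 2.0 * len(seq):
        return None
    bases, indels, span = _parse_alignment(aln, oriented)
    return AlignedRead(
        read_id=read.id,
        orientation=orientation,
        span=span,
        bases=bases,
        indels=indels,
        score=float(score),
    )


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------


def _indel_overlaps(indel: tuple[str, int, int, str], coords: set[int]) -> bool:
    kind, pos, length, _ = indel
    if kind == "del":
        return any(p in coords for p in range(pos, pos + length))
    # insertion at the junction before `pos`: overlaps if either flank is in
    return pos in coords or (pos - 1) in coords


def _is_indel_read(aligned: AlignedRead, target: AmpliconTarget) -> bool:
    coords = {target.proto_to_amplicon(p) for p in indel_window(target)}
    return any(_indel_overlaps(i, coords) for i in aligned.indels)


@dataclass
class EditingTable:
    """Per-position substitution percentages plus read-class percentages."""

    target_id: str
    substitutions: pd.DataFrame  # index: protospacer position; columns A,C,G,T
    reference_bases: dict[int, str]
    indel_pct: float
    substitution_only_pct: float
    unmodified_pct: float
    n_passing: int
    n_failing: int
    deletion_lengths: dict[int, int] = field(default_factory=dict)
    insertion_lengths: dict[int, int] = field(default_factory=dict)
    convention: str = ""

    def percent(self, position: int, base: str) -> float:
        return float(self.substitutions.loc[position, base])


def quantify_substitutions(
    aligned_reads: list[AlignedRead],
    target: AmpliconTarget,
    n_failing: int = 0,
) -> EditingTable:
    """Score substitutions per protospacer window position.

    For every window position and base b != reference: the percentage of
    passing reads that are gap-free at that position (and not in the indel
    class) carrying b.  Reads whose alignment has an indel overlapping the
    indel window form the indel class and are excluded from substitution
    denominators.  Classes partition the passing reads:
    indel + substitution-only + unmodified = 100%.
    """
    if not aligned_reads:
        raise InputError("no passing reads to quantify")
    window = quantification_window(target)
    coords = {p: target.proto_to_amplicon(p) for p in window}
    ref = {p: target.protospacer[p - 1] for p in window}

    n = len(aligned_reads)
    counts = {p: {b: 0 for b in "ACGT"} for p in window}
    denom = {p: 0 for p in window}
    n_indel = 0
    n_sub_only = 0
    del_hist: dict[int, int] = {}
    ins_hist: dict[int, int] = {}
    indel_coords = {target.proto_to_amplicon(p) for p in indel_window(target)}

    for read in aligned_reads:
        if any(_indel_overlaps(i, indel_coords) for i in read.indels):
            n_indel += 1
            for kind, pos, length, _ in read.indels:
                if _indel_overlaps((kind, pos, length, ""), indel_coords):
                    hist = del_hist if kind == "del" else ins_hist
                    hist[length] = hist.get(length, 0) + 1
            continue
        edited = False
        for p in window:
            a = coords[p]
            base = read.bases.get(a)
            if base is None:
                continue  # gap or uncovered at this position
            denom[p] += 1
            oriented = target.read_base_to_proto(base)
            if oriented != ref[p]:
                counts[p][oriented] += 1
                edited = True
        if edited:
            n_sub_only += 1

    table = pd.DataFrame(
        {b: [100.0 * counts[p][b] / denom[p] if denom[p] else 0.0 for p in window] for b in "ACGT"},
        index=pd.Index(window, name="protospacer_position"),
    )
    for p in window:
        table.loc[p, ref[p]] = 0.0

    return EditingTable(
        target_id=target.target_id,
        substitutions=table,
        reference_bases=ref,
        indel_pct=100.0 * n_indel / n,
        substitution_only_pct=100.0 * n_sub_only / n,
        unmodified_pct=100.0 * (n - n_indel - n_sub_only) / n,
        n_passing=n,
        n_failing=n_failing,
        deletion_lengths=del_hist,
        insertion_lengths=ins_hist,
        convention=target.numbering_convention,
    )


def quantify_indels(
    aligned_reads: list[AlignedRead], target: AmpliconTarget
) -> tuple[float, dict[int, int], dict[int, int]]:
    """Percent of passing reads with an insertion/deletion overlapping the
    indel window, plus deletion and insertion length histograms."""
    if not aligned_reads:
        raise InputError("no passing reads to quantify")
    coords = {target.proto_to_amplicon(p) for p in indel_window(target)}
    n_indel = 0
    del_hist: dict[int, int] = {}
    ins_hist: dict[int, int] = {}
    for read in aligned_reads:
        hits = [i for i in read.indels if _indel_overlaps(i, coords)]
        if hits:
            n_indel += 1
            for kind, _, length, _ in hits:
                hist = del_hist if kind == "del" else ins_hist
                hist[length] = hist.get(length, 0) + 1
    return 100.0 * n_indel / len(aligned_reads), del_hist, ins_hist


def allele_table(aligned_reads: list[AlignedRead], target: AmpliconTarget) -> pd.DataFrame:
    """Group passing reads by their quantification-window haplotype.

    The haplotype string reads 5'->3' along the protospacer window; deleted
    positions are '-', positions not covered by the read are '.', and an
    insertion inside the window is appended as ``+SEQ``.  Rows are sorted by
    count descending, ties broken by sequence; the annotation column lists
    each deviation from the reference.
    """
    if not aligned_reads:
        raise InputError("no passing reads to tabulate")
    window = quantification_window(target)
    coords = {p: target.proto_to_amplicon(p) for p in window}
    coord_set = set(coords.values())
    ref = {p: target.protospacer[p - 1] for p in window}

    groups: dict[str, int] = {}
    annos: dict[str, str] = {}
    for read in aligned_reads:
        deleted = set()
        for kind, pos, length, _ in read.indels:
            if kind == "del":
                deleted.update(range(pos, pos + length))
        chars = []
        notes = []
        for p in window:
            a = coords[p]
            if a in deleted:
                chars.append("-")
                continue
            base = read.bases.get(a)
            if base is None:
                chars.append(".")
                continue
            oriented = target.read_base_to_proto(base)
            chars.append(oriented)
            if oriented != ref[p]:
                notes.append(f"{ref[p]}{p}{oriented}")
        hap = "".join(chars)
        for kind, pos, length, seq in sorted(read.indels):
            if _indel_overlaps((kind, pos, length, seq), coord_set):
                if kind == "ins":
                    hap += f"+{target.read_base_to_proto(seq) if target.strand == '-' else seq}"
                    notes.append(f"ins{length}")
                else:
                    notes.append(f"del{length}")
        groups[hap] = groups.get(hap, 0) + 1
        annos.setdefault(hap, ";".join(notes) if notes else "reference")

    total = len(aligned_reads)
    rows = sorted(groups.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "haplotype": [h for h, _ in rows],
            "count": [c for _, c in rows],
            "percent": [100.0 * c / total for _, c in rows],
            "annotation": [annos[h] for h, _ in rows],
        }
    )


# ---------------------------------------------------------------------------
# zygosity and spacer-mismatch annotation
# ---------------------------------------------------------------------------


@dataclass
class ZygosityCall:
    target_id: str
    sample_id: str
    editing_rate_pct: float
    call: str  # WT, HZ or HM


def call_zygosity(
    editing_rate_pct: float, target_id: str = "", sample_id: str = ""
) -> ZygosityCall:
    """Classify a plant from its edited-read fraction.

    WT below 25%, heterozygous (HZ) for rates between 25 and 70% inclusive,
    homozygous (HM) above 70%.
    """
    if not 0.0 <= editing_rate_pct <= 100.0:
        raise InputError(f"editing rate {editing_rate_pct} outside [0, 100]")
    if editing_rate_pct < 25.0:
        call = "WT"
    elif editing_rate_pct <= 70.0:
        call = "HZ"
    else:
        call = "HM"
    return ZygosityCall(target_id, sample_id, editing_rate_pct, call)


def annotate_spacer_mismatches(
    spacer: str, locus: str, seed_length: int = 8
) -> list[tuple[int, str]]:
    """List mismatches between a spacer and a (homeolog) locus.

    Positions are 1-based 5'->3'; positions 1..seed_length are labelled
    ``seed`` (PAM-adjacent for Cas12a, where mismatches strongly suppress
    activity) and the remainder ``distal``.
    """
    spacer, locus = spacer.upper(), locus.upper()
    if len(spacer) != len(locus):
        raise InputError(
            f"spacer length {len(spacer)} != locus length {len(locus)} (no-gap comparison)"
        )
    return [
        (i + 1, "seed" if i < seed_length else "distal")
        for i, (a, b) in enumerate(zip(spacer, locus))
        if a != b
    ]


# ---------------------------------------------------------------------------
# sample-level orchestration
# ---------------------------------------------------------------------------


@dataclass
class SampleResult:
    """End-to-end quantification of one sample against one target."""

    target_id: str
    editing: EditingTable
    alleles: pd.DataFrame
    n_input: int
    n_passing: int
    n_failing: int
    n_unalignable: int


def quantify_sample(reads, target: AmpliconTarget) -> SampleResult:
    """Quality-filter, align and quantify one sample's reads."""
    reads = list(reads)
    passing, failing = quality_filter(reads, target.min_mean_quality)
    aligned = []
    n_unalignable = 0
    for read in passing:
        a = align_read(read, target)
        if a is None:
            n_unalignable += 1
        else:
            aligned.append(a)
    editing = quantify_substitutions(aligned, target, n_failing=len(failing))
    alleles = allele_table(aligned, target)
    return SampleResult(
        target_id=target.target_id,
        editing=editing,
        alleles=alleles,
        n_input=len(reads),
        n_passing=len(aligned),
        n_failing=len(failing),
        n_unalignable=n_unalignable,
    )


def assign_to_targets(
    read, targets: list[AmpliconTarget], margin: float = 10.0
) -> tuple[AmpliconTarget | None, AlignedRead | None]:
    """For multiplex panels: align a read to every amplicon and keep the best
    target when it beats the runner-up by at least ``margin`` score units."""
    scored = []
    for t in targets:
        a = align_read(read, t)
        if a is not None:
            scored.append((a.score, t, a))
    if not scored:
        return None, None
    scored.sort(key=lambda x: -x[0])
    if len(scored) > 1 and scored[0][0] - scored[1][0] < margin:
        return None, None
    return scored[0][1], scored[0][2]
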