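"""TCR clonotype decomposition of 5'-RACE amplicon reads.

Each amplicon read is expected to contain (possibly with sequencing errors)
a rearranged TCR variable region: adapter, V segment, junction insert, J
segment, and a constant-region primer tail. Reads are assigned to germline V
and J segments by local alignment, the CDR3 is delimited IMGT-style — from
the V segment's conserved second cysteine codon through the J segment's
conserved phenylalanine/tryptophan of the F/W-G-X-G motif, both inclusive —
and identical (chain, V, J, CDR3 nucleotide) rearrangements are aggregated
into clonotypes with read counts and within-chain frequencies.

Low-count clonotypes one mismatch away from a much larger clonotype with the
same V/J are absorbed into it by default, so that per-base sequencing errors
do not fragment the frequency distribution. The dominant TRA/TRB pair and a
dominance verdict summarize the repertoire of a sorted T-cell population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align, SeqIO
from Bio.Seq import Seq

CHAINS = ("TRA", "TRB")


@dataclass(frozen=True)
class GermlineSegment:
    """A germline V or J segment with its conserved CDR3 anchor.

    ``anchor_pos`` is the 1-based index of the first base of the conserved
    codon: the second cysteine (2nd-CYS) for V segments, the F/W of the
    F/W-G-X-G motif for J segments.
    """

    chain: str
    segment_type: str  # "V" or "J"
    name: str
    sequence: str
    anchor_pos: int

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise ValueError(f"chain must be one of {CHAINS}, got {self.chain!r}")
        if self.segment_type not in ("V", "J"):
            raise ValueError("segment_type must be 'V' or 'J'")
        if not 1 <= self.anchor_pos <= len(self.sequence) - 2:
            raise ValueError(f"{self.name}: anchor_pos outside sequence")
        codon = self.sequence[self.anchor_pos - 1: self.anchor_pos + 2]
        aa = str(Seq(codon).translate())
        expected = "C" if self.segment_type == "V" else "FW"
        if aa not in expected:
            raise ValueError(
                f"{self.name}: anchor codon {codon} translates to {aa}, "
                f"expected one of {expected!r}"
            )


@dataclass(frozen=True)
class AlignParams:
    """Local-alignment scoring and acceptance floors for V/J assignment.

    A segment assignment is accepted only if its local alignment score
    reaches ``floor_fraction`` of the perfect score (match_score x segment
    length), which rejects random sequence while tolerating scattered
    sequencing errors.
    """

    match_score: float = 2.0
    mismatch_score: float = -3.0
    gap_score: float = -5.0
    v_floor_fraction: float = 0.8
    j_floor_fraction: float = 0.8

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = self.match_score
        aligner.mismatch_score = self.mismatch_score
        aligner.open_gap_score = self.gap_score
        aligner.extend_gap_score = self.gap_score
        return aligner

    def floor(self, segment: GermlineSegment) -> float:
        frac = self.v_floor_fraction if segment.segment_type == "V" else self.j_floor_fraction
        return frac * self.match_score * len(segment.sequence)


@dataclass
class ChainAssignment:
    """One read's V/J assignment and extracted CDR3."""

    read_id: str
    chain: str
    v_name: str
    j_name: str
    v_score: float
    j_score: float
    cdr3_nt: str
    cdr3_aa: str  # empty when out of frame
    productive: bool


@dataclass
class Clonotype:
    """A unique rearrangement (chain, V, J, CDR3) with its abundance."""

    chain: str
    v_name: str
    j_name: str
    cdr3_nt: str
    cdr3_aa: str
    read_count: int
    frequency: float = 0.0
    productive: bool = True


class NoCdr3Error(ValueError):
    """CDR3 anchors could not be located on the read; carries a reason code."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def assign_vj(
    read: str,
    reference: Sequence[GermlineSegment],
    chain: str,
    params: AlignParams = AlignParams(),
) -> tuple[str, str, float, float] | None:
    """Best-scoring V and J assignment of a read for one chain.

    Every V and every J of the chain is locally aligned against the read;
    the highest score wins, ties broken by lexicographically smaller segment
    name. Returns ``(v_name, j_name, v_score, j_score)``, or None when either
    best score falls below its acceptance floor.
    """
    vs = [s for s in reference if s.chain == chain and s.segment_type == "V"]
    js = [s for s in reference if s.chain == chain and s.segment_type == "J"]
    if not vs or not js:
        raise ValueError(f"reference must contain at least one V and one J for {chain}")
    aligner = params.aligner()

    def best(segments: list[GermlineSegment]) -> tuple[GermlineSegment, float]:
        top, top_score = None, float("-inf")
        for seg in sorted(segments, key=lambda s: s.name):
            score = aligner.score(read, seg.sequence)
            if score > top_score:
                top, top_score = seg, score
        return top, top_score

    v_seg, v_score = best(vs)
    j_seg, j_score = best(js)
    if v_score < params.floor(v_seg) or j_score < params.floor(j_seg):
        return None
    return v_seg.name, j_seg.name, v_score, j_score


def _map_segment_pos(alignment, seg_pos0: int) -> int | None:
    """Map a 0-based segment coordinate to a read coordinate via the alignment.

    The segment is the alignment query, the read the target. Returns None if
    the position (or its codon start) is not inside an aligned block.
    """
    t_blocks, q_blocks = alignment.aligned
    for (t_start, t_end), (q_start, q_end) in zip(t_blocks, q_blocks):
        if q_start <= seg_pos0 < q_end:
            return t_start + (seg_pos0 - q_start)
    return None


def extract_cdr3(
    read: str,
    v_segment: GermlineSegment,
    j_segment: GermlineSegment,
    params: AlignParams = AlignParams(),
) -> tuple[str, str, bool]:
    """Delimit the CDR3 on a read given its assigned V and J segments.

    The CDR3 runs from the first base of the V 2nd-CYS codon through the last
    base of the J F/W codon, both located on the read by mapping the segment
    anchor coordinates through the local alignments. Returns
    ``(cdr3_nt, cdr3_aa, productive)``; ``cdr3_aa`` is empty and productive
    False when the span is out of frame or contains a stop. Raises
    :class:`NoCdr3Error` when an anchor cannot be located.
    """
    aligner = params.aligner()
    v_aln = aligner.align(read, v_segment.sequence)[0]
    j_aln = aligner.align(read, j_segment.sequence)[0]

    v_read0 = _map_segment_pos(v_aln, v_segment.anchor_pos - 1)
    if v_read0 is None:
        raise NoCdr3Error("v_anchor_unaligned")
    j_read0 = _map_segment_pos(j_aln, j_segment.anchor_pos - 1)
    if j_read0 is None:
        raise NoCdr3Error("j_anchor_unaligned")
    end = j_read0 + 3
    if end > len(read):
        raise NoCdr3Error("j_anchor_truncated")
    if j_read0 <= v_read0:
        raise NoCdr3Error("anchors_out_of_order")

    cdr3_nt = read[v_read0:end]
    if len(cdr3_nt) % 3 != 0:
        return cdr3_nt, "", False
    cdr3_aa = str(Seq(cdr3_nt).translate())
    if "*" in cdr3_aa:
        return cdr3_nt, cdr3_aa, False
    return cdr3_nt, cdr3_aa, True


def analyze_read(
    read_id: str,
    read: str,
    reference: Sequence[GermlineSegment],
    chains: Sequence[str] = CHAINS,
    params: AlignParams = AlignParams(),
) -> ChainAssignment | None:
    """Assign a read to a chain, V/J pair and CDR3; None when unassignable.

    When both chains are allowed the one with the higher combined V+J score
    (accepted assignments only) wins.
    """
    by_name = {(s.chain, s.segment_type, s.name): s for s in reference}
    best: ChainAssignment | None = None
    best_total = float("-inf")
    for chain in chains:
        hit = assign_vj(read, reference, chain, params)
        if hit is None:
            continue
        v_name, j_name, v_score, j_score = hit
        if v_score + j_score <= best_total:
            continue
        try:
            cdr3_nt, cdr3_aa, productive = extract_cdr3(
                read,
                by_name[(chain, "V", v_name)],
                by_name[(chain, "J", j_name)],
                params,
            )
        except NoCdr3Error:
            continue
        best = ChainAssignment(
            read_id, chain, v_name, j_name, v_score, j_score,
            cdr3_nt, cdr3_aa, productive,
        )
        best_total = v_score + j_score
    return best


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def aggregate_clonotypes(
    assignments: Iterable[ChainAssignment],
    error_correct: bool = True,
    max_mismatches: int = 1,
    max_child_ratio: float = 0.2,
) -> dict[str, list[Clonotype]]:
    """Group chain assignments into per-chain clonotype tables.

    Clonotype identity is (chain, V, J, CDR3 nucleotide sequence). With
    ``error_correct``, a clonotype is absorbed into a larger one sharing
    chain, V, J and CDR3 length when the sequences differ by at most
    ``max_mismatches`` bases and its count is at most ``max_child_ratio`` of
    the larger count — the signature of sequencing-error satellites around a
    real clonotype. Frequencies are fractions of all assigned reads of the
    chain; tables are sorted by descending frequency, ties by CDR3.
    """
    groups: dict[tuple[str, str, str, str], Clonotype] = {}
    for a in assignments:
        key = (a.chain, a.v_name, a.j_name, a.cdr3_nt)
        clone = groups.get(key)
        if clone is None:
            groups[key] = Clonotype(
                a.chain, a.v_name, a.j_name, a.cdr3_nt, a.cdr3_aa, 1,
                productive=a.productive,
            )
        else:
            clone.read_count += 1

    out: dict[str, list[Clonotype]] = {}
    for chain in sorted({c.chain for c in groups.values()}):
        clones = [c for c in groups.values() if c.chain == chain]
        clones.sort(key=lambda c: (-c.read_count, c.cdr3_nt))
        if error_correct:
            kept: list[Clonotype] = []
            for clone in clones:
                parent = None
                for cand in kept:
                    if (
                        cand.v_name == clone.v_name
                        and cand.j_name == clone.j_name
                        and len(cand.cdr3_nt) == len(clone.cdr3_nt)
                        and clone.read_count <= max_child_ratio * cand.read_count
                        and _hamming(cand.cdr3_nt, clone.cdr3_nt) <= max_mismatches
                    ):
                        parent = cand
                        break
                if parent is None:
                    kept.append(clone)
                else:
                    parent.read_count += clone.read_count
            clones = kept
        total = sum(c.read_count for c in clones)
        for c in clones:
            c.frequency = c.read_count / total
        clones.sort(key=lambda c: (-c.frequency, c.cdr3_nt))
        out[chain] = clones
    return out


def dominant_pair(
    tra: Sequence[Clonotype],
    trb: Sequence[Clonotype],
    dominance_threshold: float = 0.5,
) -> tuple[Clonotype, Clonotype, bool]:
    """Top TRA and TRB clonotypes with a dominance verdict.

    A repertoire is called dominated by a single clone when the top clonotype
    of each chain holds at least ``dominance_threshold`` of its chain's
    reads. Inputs are assumed sorted as produced by
    :func:`aggregate_clonotypes` (descending frequency, ties by CDR3), which
    makes the tie-break deterministic.
    """
    if not tra or not trb:
        raise ValueError("both TRA and TRB clonotype lists must be non-empty")
    top_a = min(tra, key=lambda c: (-c.frequency, c.cdr3_nt))
    top_b = min(trb, key=lambda c: (-c.frequency, c.cdr3_nt))
    dominant = top_a.frequency >= dominance_threshold and top_b.frequency >= dominance_threshold
    return top_a, top_b, dominant


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

ANCHOR_COLUMNS = ("name", "chain", "type", "anchor_pos")
CLONOTYPE_COLUMNS = ("chain", "v", "j", "cdr3_nt", "cdr3_aa", "count", "frequency", "productive")


def read_germline(fasta_path: str | Path, anchors_path: str | Path) -> list[GermlineSegment]:
    """Load a germline segment set from FASTA plus an anchor sidecar TSV.

    The TSV columns are name, chain, type (V/J) and the 1-based anchor codon
    start. Every FASTA record must have an anchor row and vice versa.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    segments: list[GermlineSegment] = []
    seen: set[str] = set()
    with Path(anchors_path).open() as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != ANCHOR_COLUMNS:
            raise ValueError(f"{anchors_path}: expected columns {ANCHOR_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            name, chain, seg_type, anchor = line.rstrip("\n").split("\t")
            if name not in seqs:
                raise ValueError(f"{anchors_path}:{lineno}: no FASTA record named {name}")
            segments.append(GermlineSegment(chain, seg_type, name, seqs[name], int(anchor)))
            seen.add(name)
    missing = set(seqs) - seen
    if missing:
        raise ValueError(f"FASTA records without anchor rows: {sorted(missing)}")
    return segments


def write_germline(segments: Sequence[GermlineSegment], fasta_path: str | Path, anchors_path: str | Path) -> None:
    with Path(fasta_path).open("w") as fh:
        for seg in segments:
            fh.write(f">{seg.name}\n{seg.sequence}\n")
    with Path(anchors_path).open("w") as fh:
        fh.write("\t".join(ANCHOR_COLUMNS) + "\n")
        for seg in segments:
            fh.write(f"{seg.name}\t{seg.chain}\t{seg.segment_type}\t{seg.anchor_pos}\n")


def analyze_fastq(
    fastq_path: str | Path,
    reference: Sequence[GermlineSegment],
    params: AlignParams = AlignParams(),
) -> list[ChainAssignment]:
    """Assign every read of a FASTQ file; unassignable reads are dropped."""
    assignments: list[ChainAssignment] = []
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        a = analyze_read(rec.id, str(rec.seq).upper(), reference, params=params)
        if a is not None:
            assignments.append(a)
    return assignments


def write_clonotype_table(clonotypes: dict[str, list[Clonotype]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(CLONOTYPE_COLUMNS) + "\n")
        for chain in sorted(clonotypes):
            for c in clonotypes[chain]:
                fh.write(
                    f"{c.chain}\t{c.v_name}\t{c.j_name}\t{c.cdr3_nt}\t{c.cdr3_aa}\t"
                    f"{c.read_count}\t{c.frequency:.6f}\t{c.productive}\n"
                )


def repertoire_summary(
    clonotypes: dict[str, list[Clonotype]],
    dominance_threshold: float = 0.5,
) -> dict:
    """JSON-ready summary: per-chain totals, top pair and dominance verdict."""
    summary: dict = {
        "chains": {
            chain: {
                "n_clonotypes": len(clones),
                "n_reads": sum(c.read_count for c in clones),
            }
            for chain, clones in clonotypes.items()
        }
    }
    if clonotypes.get("TRA") and clonotypes.get("TRB"):
        top_a, top_b, dominant = dominant_pair(
            clonotypes["TRA"], clonotypes["TRB"], dominance_threshold
        )
        summary["dominant_pair"] = {
            "TRA": {"v": top_a.v_name, "j": top_a.j_name, "cdr3_nt": top_a.cdr3_nt,
                    "cdr3_aa": top_a.cdr3_aa, "frequency": top_a.frequency},
            "TRB": {"v": top_b.v_name, "j": top_b.j_name, "cdr3_nt": top_b.cdr3_nt,
                    "cdr3_aa": top_b.cdr3_aa, "frequency": top_b.frequency},
            "dominant": dominant,
            "threshold": dominance_threshold,
        }
    return summary


def write_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
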