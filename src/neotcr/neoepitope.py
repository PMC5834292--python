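"""Neoepitope candidate generation, filtering, tiering and risk flagging.

Starting from missense mutations, every 8- to 11-mer peptide window of the
mutant protein that contains the substituted residue is enumerated together
with its wild-type counterpart. Candidates are then filtered by predicted
peptide-HLA binding affinity (IC50 <= 500 nM, the conventional binder
definition), by mutant-allele RNA evidence (>= 1 read), and strong binders
(IC50 <= 50 nM) are promoted to the priming tier used to select peptides for
T-cell induction.

A cross-reactivity heuristic flags candidates whose substitution sits at an
HLA anchor position (canonically peptide positions 2 and 9 for HLA-A
alleles) while the wild-type analog still binds: such peptides present an
unchanged TCR contact surface, so a TCR raised against the mutant is likely
to recognize the wild-type peptide as well.

A deterministic position-weight-matrix (PWM) toy predictor is provided so
the pipeline runs without external binding-prediction software; real
predictions are ingested from a tab-delimited table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Pipeline tier labels and their IC50 bounds (nM), inclusive.
TIER_DISCOVERY = "discovery"  # <= 500 nM
TIER_PRIMING = "priming"  # <= 50 nM
DISCOVERY_IC50_NM = 500.0
PRIMING_IC50_NM = 50.0

PEPTIDE_LENGTHS = (8, 9, 10, 11)


class MissingPredictionError(KeyError):
    """Raised when a candidate has no affinity prediction for its peptide/HLA."""


@dataclass(frozen=True)
class MissenseMutation:
    """A single amino-acid substitution in a protein, with RNA evidence.

    ``position`` is the 1-based residue index; ``protein`` is the wild-type
    sequence (so ``protein[position-1] == ref_aa``). ``mutant_rna_reads``
    counts RNA-seq reads supporting the mutant allele.
    """

    gene: str
    protein: str
    position: int
    ref_aa: str
    alt_aa: str
    mutant_rna_reads: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.position <= len(self.protein):
            raise ValueError(
                f"{self.gene}: position {self.position} outside protein of "
                f"length {len(self.protein)}"
            )
        if self.protein[self.position - 1] != self.ref_aa:
            raise ValueError(
                f"{self.gene}: protein has {self.protein[self.position - 1]} at "
                f"position {self.position}, expected ref {self.ref_aa}"
            )
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"{self.gene}: ref and alt residues are identical")
        if self.mutant_rna_reads < 0:
            raise ValueError("mutant_rna_reads must be non-negative")

    @property
    def label(self) -> str:
        return f"{self.gene}_{self.ref_aa}{self.position}{self.alt_aa}"

    @property
    def mutant_protein(self) -> str:
        p = self.position - 1
        return self.protein[:p] + self.alt_aa + self.protein[p + 1:]


@dataclass(frozen=True)
class AffinityPrediction:
    """Predicted IC50 (nM) for one peptide on one HLA class I allele."""

    peptide: str
    hla_allele: str
    ic50_nm: float

    def __post_init__(self) -> None:
        if not 8 <= len(self.peptide) <= 11:
            raise ValueError(f"peptide length must be 8-11, got {self.peptide!r}")
        if self.ic50_nm <= 0:
            raise ValueError(f"ic50_nm must be positive, got {self.ic50_nm}")


@dataclass(frozen=True)
class HlaAnchorProfile:
    """Anchor positions of an HLA allele (1-based peptide indices).

    Positions 2 and the C-terminal anchor (9 for a 9-mer) are canonical for
    HLA-A*02:01 and HLA-A*24:02.
    """

    hla_allele: str
    anchor_positions: frozenset[int] = frozenset({2, 9})


@dataclass
class NeoepitopeCandidate:
    """A mutant peptide window with its wild-type analog and annotations."""

    gene: str
    label: str
    mut_peptide: str
    wt_peptide: str
    mut_offset: int  # 1-based index of the substituted residue in the peptide
    hla_allele: str
    mut_ic50_nm: float | None = None
    wt_ic50_nm: float | None = None
    mutant_rna_reads: int = 0
    tier: str | None = None
    cross_reactivity_risk: str | None = None

    def __post_init__(self) -> None:
        if len(self.mut_peptide) != len(self.wt_peptide):
            raise ValueError("mutant and wild-type peptides must have equal length")
        diffs = [i for i, (m, w) in enumerate(zip(self.mut_peptide, self.wt_peptide)) if m != w]
        if diffs != [self.mut_offset - 1]:
            raise ValueError(
                "peptides must differ exactly at mut_offset "
                f"({self.mut_offset}); differing positions: {[d + 1 for d in diffs]}"
            )


def locate_substitution(mut_peptide: str, wt_peptide: str) -> int:
    """1-based position at which the two equal-length peptides differ.

    Raises if they differ at no position or more than one.
    """
    if len(mut_peptide) != len(wt_peptide):
        raise ValueError("peptides must have equal length")
    diffs = [i for i, (m, w) in enumerate(zip(mut_peptide, wt_peptide)) if m != w]
    if len(diffs) != 1:
        raise ValueError(f"expected exactly one substitution, found {len(diffs)}")
    return diffs[0] + 1


# ---------------------------------------------------------------------------
# CDS-level mutation application
# ---------------------------------------------------------------------------

STOP_SYMBOL = "*"


def translate_cds(cds: str) -> str:
    """Translate a CDS (standard code), stripping one trailing stop if present.

    Raises on length not divisible by 3, invalid characters, or an internal
    stop codon.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if set(cds) - set("ACGT"):
        raise ValueError("CDS contains non-ACGT characters")
    protein = str(Seq(cds).translate())
    if protein.endswith(STOP_SYMBOL):
        protein = protein[:-1]
    if STOP_SYMBOL in protein:
        raise ValueError("reference CDS contains a premature internal stop codon")
    return protein


def apply_missense(
    cds: str,
    cds_pos: int,
    alt_base: str,
    gene: str = "GENE",
    mutant_rna_reads: int = 0,
) -> tuple[str, MissenseMutation | str]:
    """Apply a single-nucleotide change to a CDS and classify its effect.

    ``cds_pos`` is the 1-based position of the substituted nucleotide within
    the CDS. Returns ``(mutant_protein, result)`` where ``result`` is a
    :class:`MissenseMutation` for a missense change, or the verdict string
    ``"synonymous"`` / ``"stop_gain"`` / ``"stop_loss"`` otherwise (the
    mutant protein is still returned for inspection).
    """
    cds = cds.upper()
    alt_base = alt_base.upper()
    if not 1 <= cds_pos <= len(cds):
        raise ValueError(f"cds_pos {cds_pos} outside CDS of length {len(cds)}")
    if alt_base not in "ACGT":
        raise ValueError(f"alt base must be one of ACGT, got {alt_base!r}")
    if cds[cds_pos - 1] == alt_base:
        raise ValueError("alt base equals the reference base")

    ref_protein = translate_cds(cds)
    mutant_cds = cds[: cds_pos - 1] + alt_base + cds[cds_pos:]
    mutant_full = str(Seq(mutant_cds).translate())

    codon_index = (cds_pos - 1) // 3  # 0-based protein position
    mut_aa = mutant_full[codon_index]
    has_terminal_stop = len(mutant_full) > len(ref_protein)  # ref had trailing stop
    if codon_index >= len(ref_protein):
        # change within the reference stop codon
        mutant_protein = mutant_full[:-1] if mutant_full.endswith(STOP_SYMBOL) else mutant_full
        verdict = "synonymous" if mut_aa == STOP_SYMBOL else "stop_loss"
        return mutant_protein, verdict

    ref_aa = ref_protein[codon_index]
    mutant_protein = mutant_full[:-1] if has_terminal_stop and mutant_full.endswith(STOP_SYMBOL) else mutant_full
    if mut_aa == STOP_SYMBOL:
        return mutant_protein, "stop_gain"
    if mut_aa == ref_aa:
        return mutant_protein, "synonymous"
    mutation = MissenseMutation(
        gene=gene,
        protein=ref_protein,
        position=codon_index + 1,
        ref_aa=ref_aa,
        alt_aa=mut_aa,
        mutant_rna_reads=mutant_rna_reads,
    )
    return mutation.mutant_protein, mutation


# ---------------------------------------------------------------------------
# Peptide enumeration
# ---------------------------------------------------------------------------

def enumerate_mutant_peptides(
    mut: MissenseMutation,
    lengths: Iterable[int] = PEPTIDE_LENGTHS,
) -> list[tuple[str, str, int]]:
    """All peptide windows of the mutant protein containing the substitution.

    For each length L, every window of the mutant protein that covers the
    substituted residue is emitted (windows are clipped at the protein
    termini, so positions near an end yield fewer windows). Returns
    ``(mut_peptide, wt_peptide, mut_offset)`` tuples with ``mut_offset`` the
    1-based index of the substituted residue inside the peptide; ordered by
    (length, window start), without duplicates.
    """
    mutant = mut.mutant_protein
    wild = mut.protein
    n = len(wild)
    p = mut.position  # 1-based
    out: list[tuple[str, str, int]] = []
    seen: set[tuple[str, str, int]] = set()
    for L in sorted(set(lengths)):
        first = max(1, p - L + 1)
        last = min(p, n - L + 1)
        for start in range(first, last + 1):  # 1-based window start
            window = (
                mutant[start - 1: start - 1 + L],
                wild[start - 1: start - 1 + L],
                p - start + 1,
            )
            if window not in seen:
                seen.add(window)
                out.append(window)
    return out


def candidates_from_mutation(
    mut: MissenseMutation,
    hla_allele: str,
    lengths: Iterable[int] = PEPTIDE_LENGTHS,
) -> list[NeoepitopeCandidate]:
    """Wrap enumerated windows of one mutation as unfiltered candidates."""
    return [
        NeoepitopeCandidate(
            gene=mut.gene,
            label=mut.label,
            mut_peptide=mp,
            wt_peptide=wp,
            mut_offset=off,
            hla_allele=hla_allele,
            mutant_rna_reads=mut.mutant_rna_reads,
        )
        for mp, wp, off in enumerate_mutant_peptides(mut, lengths)
    ]


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _lookup_ic50(
    predictions: Mapping[tuple[str, str], float],
    peptide: str,
    hla_allele: str,
) -> float:
    try:
        return predictions[(peptide, hla_allele)]
    except KeyError:
        raise MissingPredictionError(
            f"no affinity prediction for peptide {peptide} on {hla_allele}"
        ) from None


def prediction_map(predictions: Iterable[AffinityPrediction]) -> dict[tuple[str, str], float]:
    """Index predictions by (peptide, allele) for filter lookups."""
    return {(p.peptide, p.hla_allele): p.ic50_nm for p in predictions}


def filter_by_affinity(
    candidates: Sequence[NeoepitopeCandidate],
    predictions: Mapping[tuple[str, str], float],
    threshold_nm: float = DISCOVERY_IC50_NM,
) -> list[NeoepitopeCandidate]:
    """Keep candidates whose mutant-peptide IC50 is <= threshold (inclusive).

    Fills ``mut_ic50_nm`` and assigns the tier label corresponding to the
    strongest threshold met (priming <= 50 nM, else discovery <= 500 nM).
    A candidate lacking a prediction raises :class:`MissingPredictionError`.
    """
    kept: list[NeoepitopeCandidate] = []
    for cand in candidates:
        ic50 = _lookup_ic50(predictions, cand.mut_peptide, cand.hla_allele)
        cand.mut_ic50_nm = ic50
        if ic50 <= threshold_nm:
            if ic50 <= PRIMING_IC50_NM:
                cand.tier = TIER_PRIMING
            elif ic50 <= DISCOVERY_IC50_NM:
                cand.tier = TIER_DISCOVERY
            kept.append(cand)
    return kept


def filter_by_expression(
    candidates: Sequence[NeoepitopeCandidate], min_reads: int = 1
) -> list[NeoepitopeCandidate]:
    """Keep candidates with mutant RNA evidence of at least ``min_reads``."""
    return [c for c in candidates if c.mutant_rna_reads >= min_reads]


def flag_cross_reactivity(
    candidate: NeoepitopeCandidate,
    anchors: HlaAnchorProfile,
    wt_affinity_threshold_nm: float = DISCOVERY_IC50_NM,
) -> str:
    """Label the cross-reactivity risk of a candidate as ``high`` or ``low``.

    Risk is high iff the substitution sits at an HLA anchor position and the
    wild-type analog also binds (wt IC50 <= threshold): the anchor change
    leaves the TCR-facing surface identical between mutant and wild-type
    peptide, so mutant-raised TCRs are likely cross-reactive. The label is
    stored on the candidate and returned.
    """
    if candidate.wt_ic50_nm is None:
        raise ValueError("wt_ic50_nm must be populated before risk flagging")
    risky = (
        candidate.mut_offset in anchors.anchor_positions
        and candidate.wt_ic50_nm <= wt_affinity_threshold_nm
    )
    candidate.cross_reactivity_risk = "high" if risky else "low"
    return candidate.cross_reactivity_risk


# ---------------------------------------------------------------------------
# Toy PWM affinity predictor
# ---------------------------------------------------------------------------

@dataclass
class ToyPwm:
    """Deterministic position-weight-matrix affinity model.

    For a peptide p of length L, IC50(p) = scale_L * exp(-sum_i S_L[i][p_i])
    with scale_L chosen so the consensus peptide (the argmax residue at each
    position) scores ``min_ic50_nm`` exactly. A peptide whose residues all
    score zero therefore gets the baseline IC50 ``scale_L``.
    """

    hla_allele: str
    matrices: dict[int, list[dict[str, float]]]  # length -> per-position scores
    min_ic50_nm: float = 1.0

    def __post_init__(self) -> None:
        for L, matrix in self.matrices.items():
            if len(matrix) != L:
                raise ValueError(f"matrix for length {L} has {len(matrix)} positions")
            for col in matrix:
                missing = set(AMINO_ACIDS) - set(col)
                if missing:
                    raise ValueError(f"matrix column missing residues: {sorted(missing)}")

    def _scale(self, length: int) -> float:
        matrix = self.matrices[length]
        best = sum(max(col.values()) for col in matrix)
        return self.min_ic50_nm * math.exp(best)

    def consensus(self, length: int) -> str:
        """The maximal-scoring peptide of the given length."""
        return "".join(
            min((aa for aa in AMINO_ACIDS), key=lambda a: (-col[a], a))
            for col in self.matrices[length]
        )

    def baseline_ic50(self, length: int) -> float:
        """IC50 of a peptide whose residues all score zero."""
        return self._scale(length)

    def predict(self, peptide: str) -> AffinityPrediction:
        peptide = peptide.upper()
        if len(peptide) not in self.matrices:
            raise ValueError(f"no matrix for peptide length {len(peptide)}")
        matrix = self.matrices[len(peptide)]
        total = 0.0
        for i, aa in enumerate(peptide):
            if aa not in matrix[i]:
                raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
            total += matrix[i][aa]
        ic50 = self._scale(len(peptide)) * math.exp(-total)
        return AffinityPrediction(peptide, self.hla_allele, ic50)


#: Residue preferences used to build the built-in toy PWMs. Position 2 and
#: the C-terminal position are the HLA anchor columns.
_ANCHOR2 = {"HLA-A*02:01": "LM", "HLA-A*24:02": "YF"}
_ANCHOR_C = {"HLA-A*02:01": "VL", "HLA-A*24:02": "FLI"}
_HYDROPHOBIC = "AILMFVWY"


def builtin_pwm(hla_allele: str, min_ic50_nm: float = 1.0) -> ToyPwm:
    """A deterministic toy PWM for an HLA-A allele, lengths 8-11.

    Anchor columns (position 2 and the C terminus) score the allele's
    preferred residues highly; other columns mildly favor hydrophobic
    residues. This is a pedagogical stand-in for a trained predictor: it is
    deterministic and rank-sensible, not an accurate affinity model.
    """
    p2 = _ANCHOR2.get(hla_allele, "LM")
    pc = _ANCHOR_C.get(hla_allele, "VL")
    matrices: dict[int, list[dict[str, float]]] = {}
    for L in PEPTIDE_LENGTHS:
        cols = []
        for i in range(L):
            if i == 1:
                col = {aa: (4.0 if aa in p2 else 0.5 if aa in _HYDROPHOBIC else 0.0) for aa in AMINO_ACIDS}
            elif i == L - 1:
                col = {aa: (4.0 if aa in pc else 0.5 if aa in _HYDROPHOBIC else 0.0) for aa in AMINO_ACIDS}
            else:
                col = {aa: (0.6 if aa in _HYDROPHOBIC else 0.2 if aa in "STNQ" else 0.0) for aa in AMINO_ACIDS}
            cols.append(col)
        matrices[L] = cols
    return ToyPwm(hla_allele, matrices, min_ic50_nm)


def toy_pwm_predict(peptide: str, hla_allele: str, pwm: ToyPwm | None = None) -> AffinityPrediction:
    """Predict IC50 for one peptide with a toy PWM (built-in if none given)."""
    if pwm is None:
        pwm = builtin_pwm(hla_allele)
    if pwm.hla_allele != hla_allele:
        raise ValueError(f"PWM is for {pwm.hla_allele}, requested {hla_allele}")
    return pwm.predict(peptide)


# ---------------------------------------------------------------------------
# Affinity table I/O
# ---------------------------------------------------------------------------

AFFINITY_COLUMNS = ("peptide", "hla_allele", "ic50_nm")


def parse_affinity_table(path: str | Path) -> list[AffinityPrediction]:
    """Read a tab-delimited affinity table: peptide, hla_allele, ic50_nm.

    The layout mirrors the essential columns of binding-predictor output.
    Malformed rows (wrong field count, nonpositive or non-numeric IC50, bad
    peptide) raise with the offending line number.
    """
    path = Path(path)
    predictions: list[AffinityPrediction] = []
    with path.open() as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != AFFINITY_COLUMNS:
            raise ValueError(f"{path}: expected columns {AFFINITY_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            peptide, allele, ic50_s = fields
            try:
                ic50 = float(ic50_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric IC50 {ic50_s!r}") from None
            try:
                predictions.append(AffinityPrediction(peptide, allele, ic50))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return predictions


def write_affinity_table(predictions: Iterable[AffinityPrediction], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(AFFINITY_COLUMNS) + "\n")
        for p in predictions:
            fh.write(f"{p.peptide}\t{p.hla_allele}\t{p.ic50_nm:.4f}\n")


# ---------------------------------------------------------------------------
# Pipeline over a mutation list
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = (
    "gene", "label", "hla", "mut_peptide", "wt_peptide", "mut_offset",
    "mut_ic50_nm", "wt_ic50_nm", "rna_reads", "tier", "risk",
)


def screen_mutations(
    mutations: Sequence[MissenseMutation],
    hla_allele: str,
    predictions: Mapping[tuple[str, str], float] | None = None,
    pwm: ToyPwm | None = None,
    anchors: HlaAnchorProfile | None = None,
    lengths: Iterable[int] = PEPTIDE_LENGTHS,
    priming_only: bool = False,
) -> list[NeoepitopeCandidate]:
    """Run the full screening order over a mutation list for one HLA allele.

    Order: enumerate all windows; keep mutant IC50 <= 500 nM; keep mutant RNA
    evidence >= 1 read; assign the priming tier (IC50 <= 50 nM); annotate
    wild-type IC50 and the anchor-position cross-reactivity risk of every
    survivor. ``predictions`` takes precedence; peptides absent from it fall
    back to ``pwm`` when one is given, otherwise raise.
    """
    if predictions is None and pwm is None:
        raise ValueError("either an affinity table or a toy PWM is required")
    anchors = anchors or HlaAnchorProfile(hla_allele)

    def ic50_of(peptide: str) -> float:
        if predictions is not None and (peptide, hla_allele) in predictions:
            return predictions[(peptide, hla_allele)]
        if pwm is not None:
            return pwm.predict(peptide).ic50_nm
        return _lookup_ic50(predictions, peptide, hla_allele)

    candidates: list[NeoepitopeCandidate] = []
    for mut in mutations:
        candidates.extend(candidates_from_mutation(mut, hla_allele, lengths))

    table = {(c.mut_peptide, hla_allele): ic50_of(c.mut_peptide) for c in candidates}
    kept = filter_by_affinity(candidates, table, DISCOVERY_IC50_NM)
    kept = filter_by_expression(kept)
    if priming_only:
        kept = [c for c in kept if c.tier == TIER_PRIMING]
    for cand in kept:
        cand.wt_ic50_nm = ic50_of(cand.wt_peptide)
        flag_cross_reactivity(cand, anchors)
    return kept


def candidates_to_rows(candidates: Iterable[NeoepitopeCandidate]) -> list[dict]:
    """Flatten candidates to the documented output-table columns."""
    rows = []
    for c in candidates:
        rows.append({
            "gene": c.gene,
            "label": c.label,
            "hla": c.hla_allele,
            "mut_peptide": c.mut_peptide,
            "wt_peptide": c.wt_peptide,
            "mut_offset": c.mut_offset,
            "mut_ic50_nm": c.mut_ic50_nm,
            "wt_ic50_nm": c.wt_ic50_nm,
            "rna_reads": c.mutant_rna_reads,
            "tier": c.tier,
            "risk": c.cross_reactivity_risk,
        })
    return rows
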