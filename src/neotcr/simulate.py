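"""Seeded synthetic data with known truth for every pipeline stage.

Three generators emulate the statistical structure of the real inputs:

* :func:`simulate_pileups` — tumor/normal pileup columns with binomially
  sampled variant alleles, uniform substitution sequencing errors, and
  Phred qualities correlated with error status (miscalled bases are drawn
  with lower base qualities, which is what makes a base-quality cutoff an
  effective error filter).
* :func:`simulate_mutated_proteome` — random coding sequences with planted
  single-nucleotide missense changes and mutant RNA read counts; a specific
  peptide can be embedded around the substitution for fixture tests.
* :func:`simulate_repertoire_reads` — 5'-RACE-style TCR amplicon reads
  (adapter + V + junction insert + J + constant-region stub) drawn from a
  clone mixture with per-base substitution errors.

All generators are pure functions of their spec and seed: the same seed
reproduces byte-identical output files. Truth tables accompany every output
so downstream stages can be scored without re-reading generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .somatic import PileupSite, ReadObservation
from .repertoire import GermlineSegment

BASES = "ACGT"
#: Sense codons of the standard code (no stops), in a fixed order.
SENSE_CODONS = tuple(
    a + b + c
    for a in "TCAG" for b in "TCAG" for c in "TCAG"
    if a + b + c not in ("TAA", "TAG", "TGA")
)


# ---------------------------------------------------------------------------
# Pileup simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PileupSimSpec:
    """Conditions for tumor/normal pileup simulation.

    Defaults are the caller-recovery study conditions: 1,000 sites of which
    100 carry a planted variant at VAF 0.20, mean depth 100 in both samples,
    1% per-base sequencing error.
    """

    seed: int
    n_sites: int = 1000
    n_variants: int = 100
    true_vaf: float = 0.20
    tumor_depth_mean: float = 100.0
    normal_depth_mean: float = 100.0
    error_rate: float = 0.01
    read_length: int = 100
    #: P(high quality) for correctly called vs miscalled bases; high = Q37,
    #: low = Q12 (below the Q15 criterion).
    p_high_quality_correct: float = 0.95
    p_high_quality_error: float = 0.25
    p_good_mapq: float = 0.97

    def __post_init__(self) -> None:
        for name in ("true_vaf", "error_rate", "p_high_quality_correct",
                     "p_high_quality_error", "p_good_mapq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_variants > self.n_sites:
            raise ValueError("cannot plant more variants than sites")


def _draw_observation(
    rng: np.random.Generator,
    true_base: str,
    spec: PileupSimSpec,
) -> ReadObservation:
    is_error = rng.random() < spec.error_rate
    if is_error:
        others = [b for b in BASES if b != true_base]
        base = others[rng.integers(0, 3)]
        p_high = spec.p_high_quality_error
    else:
        base = true_base
        p_high = spec.p_high_quality_correct
    base_q = 37 if rng.random() < p_high else 12
    mapq = 60 if rng.random() < spec.p_good_mapq else 20
    mism = int(rng.poisson(1.0))
    return ReadObservation(base, base_q, mapq, spec.read_length, min(mism, spec.read_length))


def simulate_pileups(spec: PileupSimSpec) -> tuple[list[PileupSite], pd.DataFrame]:
    """Simulate pileup sites and return them with the planted-variant truth.

    Tumor reads at a planted site carry the alt allele with probability
    ``true_vaf`` before sequencing error; normal reads never carry it. The
    truth table columns are chrom, pos, ref, alt, true_vaf.
    """
    rng = np.random.default_rng(spec.seed)
    variant_idx = set(rng.choice(spec.n_sites, size=spec.n_variants, replace=False).tolist())
    sites: list[PileupSite] = []
    truth_rows = []
    for i in range(spec.n_sites):
        ref = BASES[rng.integers(0, 4)]
        alt = None
        if i in variant_idx:
            alt = [b for b in BASES if b != ref][rng.integers(0, 3)]
            truth_rows.append({
                "chrom": "chr1", "pos": i + 1, "ref": ref, "alt": alt,
                "true_vaf": spec.true_vaf,
            })
        t_depth = max(1, int(rng.poisson(spec.tumor_depth_mean)))
        n_depth = max(1, int(rng.poisson(spec.normal_depth_mean)))
        tumor = [
            _draw_observation(
                rng,
                alt if alt is not None and rng.random() < spec.true_vaf else ref,
                spec,
            )
            for _ in range(t_depth)
        ]
        normal = [_draw_observation(rng, ref, spec) for _ in range(n_depth)]
        sites.append(PileupSite("chr1", i + 1, ref, tumor, normal))
    truth = pd.DataFrame(truth_rows, columns=["chrom", "pos", "ref", "alt", "true_vaf"])
    return sites, truth


def write_pileup_tsv(sites: Sequence[PileupSite], sample: str, path: str | Path) -> None:
    """Write one sample's observations in the per-observation TSV dialect."""
    attr = {"tumor": "tumor_obs", "normal": "normal_obs"}[sample]
    with Path(path).open("w") as fh:
        fh.write("chrom\tpos\tref\tbase\tbase_qual\tmapq\tread_len\tn_mismatch\n")
        for site in sites:
            for o in getattr(site, attr):
                fh.write(
                    f"{site.chrom}\t{site.pos}\t{site.ref_allele}\t{o.base}\t"
                    f"{o.base_quality}\t{o.mapping_quality}\t{o.read_length}\t{o.mismatch_count}\n"
                )


# ---------------------------------------------------------------------------
# Mutated proteome simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbeddedPeptide:
    """Request to embed a specific mutant peptide around a planted change.

    The mutant protein will contain ``peptide``; the wild-type protein has
    ``wt_aa`` at the peptide's ``mut_offset`` (1-based) instead, and the
    planted CDS change converts the one into the other with a single
    nucleotide substitution.
    """

    peptide: str
    mut_offset: int
    wt_aa: str

    def __post_init__(self) -> None:
        if not 1 <= self.mut_offset <= len(self.peptide):
            raise ValueError("mut_offset outside peptide")
        if self.wt_aa == self.peptide[self.mut_offset - 1]:
            raise ValueError("wild-type residue equals the mutant residue")


def _codon_pair(wt_aa: str, alt_aa: str) -> tuple[str, str]:
    """A (wt_codon, alt_codon) pair differing by exactly one nucleotide."""
    wt_codons = [c for c in SENSE_CODONS if str(Seq(c).translate()) == wt_aa]
    alt_codons = [c for c in SENSE_CODONS if str(Seq(c).translate()) == alt_aa]
    for wc in wt_codons:
        for ac in alt_codons:
            if sum(a != b for a, b in zip(wc, ac)) == 1:
                return wc, ac
    raise ValueError(f"no single-nucleotide codon path from {wt_aa} to {alt_aa}")


MUTATION_COLUMNS = ("gene", "cds_pos", "ref", "alt", "mutant_rna_reads")
MUTATION_TRUTH_COLUMNS = MUTATION_COLUMNS + ("embedded",)


def simulate_mutated_proteome(
    n_proteins: int,
    n_missense: int,
    seed: int,
    min_length: int = 100,
    max_length: int = 400,
    embed: EmbeddedPeptide | None = None,
    zero_expression_fraction: float = 0.25,
    rna_reads_mean: float = 30.0,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Random CDS set with planted single-nucleotide missense mutations.

    Lengths (in residues, excluding the stop) are uniform on
    [min_length, max_length]; each CDS starts with ATG and ends with TAA.
    Planted changes are sampled uniformly over interior codons and re-drawn
    until missense. A fraction of mutations gets zero mutant RNA reads, the
    rest 1 + Poisson(``rna_reads_mean``). With ``embed``, the first mutation
    is placed so the mutant protein contains the requested peptide.

    Returns CDS FASTA records (ids ``GENE1``...) and the mutation table
    (columns gene, cds_pos, ref, alt, mutant_rna_reads).
    """
    if min_length < 11:
        raise ValueError("protein length must be at least 11")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(min_length, max_length + 1, size=n_proteins)
    codons_per_protein = [
        ["ATG"] + [SENSE_CODONS[j] for j in rng.integers(0, len(SENSE_CODONS), size=int(L) - 1)]
        for L in lengths
    ]

    rows = []
    used: set[tuple[int, int]] = set()

    def rna_reads() -> int:
        if rng.random() < zero_expression_fraction:
            return 0
        return 1 + int(rng.poisson(rna_reads_mean))

    n_random = n_missense
    if embed is not None:
        if n_missense < 1:
            raise ValueError("embedding a peptide requires n_missense >= 1")
        pep = embed.peptide
        if len(pep) + 2 > int(lengths[0]):
            raise ValueError("requested peptide longer than the first protein")
        codons = codons_per_protein[0]
        # place the peptide away from start/stop; codon index of residue 1
        start = 1 + int(rng.integers(1, int(lengths[0]) - len(pep) - 1))
        wt_codon, alt_codon = _codon_pair(embed.wt_aa, pep[embed.mut_offset - 1])
        for k, aa in enumerate(pep):
            if k == embed.mut_offset - 1:
                codons[start + k] = wt_codon
            else:
                wcs = [c for c in SENSE_CODONS if str(Seq(c).translate()) == aa]
                codons[start + k] = wcs[int(rng.integers(0, len(wcs)))]
        codon_idx = start + embed.mut_offset - 1
        within = next(i for i in range(3) if wt_codon[i] != alt_codon[i])
        rows.append({
            "gene": "GENE1",
            "cds_pos": codon_idx * 3 + within + 1,
            "ref": wt_codon[within],
            "alt": alt_codon[within],
            "mutant_rna_reads": max(1, rna_reads()),
            "embedded": True,
        })
        used.add((0, codon_idx))
        n_random -= 1

    attempts = 0
    while n_random > 0:
        attempts += 1
        if attempts > 10000 * n_missense + 100:
            raise RuntimeError("could not place the requested number of missense mutations")
        pi = int(rng.integers(0, n_proteins))
        codons = codons_per_protein[pi]
        ci = int(rng.integers(1, len(codons)))  # never the ATG
        if (pi, ci) in used:
            continue
        codon = codons[ci]
        within = int(rng.integers(0, 3))
        ref_base = codon[within]
        alt_base = [b for b in BASES if b != ref_base][int(rng.integers(0, 3))]
        new_codon = codon[:within] + alt_base + codon[within + 1:]
        if new_codon not in SENSE_CODONS:
            continue  # stop-gain
        if str(Seq(new_codon).translate()) == str(Seq(codon).translate()):
            continue  # synonymous
        used.add((pi, ci))
        rows.append({
            "gene": f"GENE{pi + 1}",
            "cds_pos": ci * 3 + within + 1,
            "ref": ref_base,
            "alt": alt_base,
            "mutant_rna_reads": rna_reads(),
            "embedded": False,
        })
        n_random -= 1

    records = [
        SeqRecord(Seq("".join(codons) + "TAA"), id=f"GENE{i + 1}", description="synthetic CDS")
        for i, codons in enumerate(codons_per_protein)
    ]
    table = pd.DataFrame(rows, columns=MUTATION_TRUTH_COLUMNS)
    table = table.sort_values(["gene", "cds_pos"], kind="stable").reset_index(drop=True)
    return records, table


def write_mutation_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    """Read a mutation table; extra columns (e.g. truth flags) are tolerated."""
    table = pd.read_csv(path, sep="\t")
    missing = set(MUTATION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return table


# ---------------------------------------------------------------------------
# Germline fixture set
# ---------------------------------------------------------------------------

#: Synthetic 5' adapter and per-chain constant-region stubs used in reads.
ADAPTER = "ACGTGCTCTTCCGATCTGTAC"
CONSTANT_STUBS = {"TRA": "ATATCCAGAACCCTGACCCTG", "TRB": "GAGGACCTGAACAAGGTGTTC"}

_V_LENGTH = 60
_V_ANCHOR = 55  # 1-based start of the 2nd-CYS codon (TGT), 6 nt of V in CDR3
_J_ANCHOR = 10  # 1-based start of the F/W codon; 12 nt of J in CDR3
_J_PREFIX = "GACTCAGCA"  # 3 non-stop codons upstream of the F/W codon


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def builtin_germline() -> list[GermlineSegment]:
    """The in-repo synthetic germline set: 4 V and 4 J per chain.

    Segments are deterministic (fixed internal seed). V segments are 60 nt
    with the 2nd-CYS codon TGT at position 55; J segments carry the
    F/W-G-X-G motif with the F (TRA) or W (TRB) codon at position 10. These
    are structurally valid stand-ins, not IMGT alleles.
    """
    rng = np.random.default_rng(20180113)
    segments: list[GermlineSegment] = []
    for chain in ("TRA", "TRB"):
        for k in range(1, 5):
            prefix = _random_dna(rng, _V_ANCHOR - 1)
            seq = prefix + "TGT" + "GCC"
            assert len(seq) == _V_LENGTH
            segments.append(GermlineSegment(chain, "V", f"{chain}V-SYN{k}", seq, _V_ANCHOR))
        fw_codon = "TTT" if chain == "TRA" else "TGG"
        for k in range(1, 5):
            motif = fw_codon + "GGC" + SENSE_CODONS[int(rng.integers(0, len(SENSE_CODONS)))] + "GGC"
            tail = _random_dna(rng, 24)
            seq = _J_PREFIX + motif + tail
            segments.append(GermlineSegment(chain, "J", f"{chain}J-SYN{k}", seq, _J_ANCHOR))
    return segments


def truth_cdr3(
    v: GermlineSegment, j: GermlineSegment, junction_insert: str
) -> str:
    """The CDR3 nucleotide sequence implied by a rearrangement."""
    return v.sequence[v.anchor_pos - 1:] + junction_insert + j.sequence[: j.anchor_pos + 2]


# ---------------------------------------------------------------------------
# Repertoire read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainRearrangement:
    """One chain of a T-cell clone: V, J and the junction insert."""

    chain: str
    v_name: str
    j_name: str
    junction_insert: str


@dataclass(frozen=True)
class ClonePair:
    """A T-cell clone with its TRA and TRB rearrangements."""

    tra: ChainRearrangement
    trb: ChainRearrangement


def default_clone_pairs() -> list[ClonePair]:
    """Three distinct clones over the built-in germline set.

    Junction inserts are multiples of 3 nt (productive rearrangements) and
    mutually distant, so clonotypes cannot collide under single-mismatch
    error absorption.
    """
    inserts = ["GCTAGCGGT", "TTGCGTAAC", "CAACCGTGGATT"]
    pairs = []
    for i, ins in enumerate(inserts, start=1):
        k = ((i - 1) % 4) + 1
        pairs.append(ClonePair(
            tra=ChainRearrangement("TRA", f"TRAV-SYN{k}", f"TRAJ-SYN{k}", ins),
            trb=ChainRearrangement("TRB", f"TRBV-SYN{k}", f"TRBJ-SYN{k}", ins[::-1]),
        ))
    return pairs


@dataclass(frozen=True)
class RepertoireSimSpec:
    """Conditions for amplicon read simulation.

    Defaults are the repertoire-recovery study conditions: a 0.7/0.2/0.1
    clone mixture, 10,000 reads, 0.5% per-base substitution error.
    """

    seed: int
    clones: tuple[ClonePair, ...] = tuple(default_clone_pairs())
    frequencies: tuple[float, ...] = (0.7, 0.2, 0.1)
    n_reads: int = 10000
    error_rate: float = 0.005

    def __post_init__(self) -> None:
        if len(self.clones) != len(self.frequencies):
            raise ValueError("one frequency per clone is required")
        if any(f < 0 for f in self.frequencies):
            raise ValueError("frequencies must be non-negative")
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")


def _clean_read(
    rearr: ChainRearrangement, segments: dict[tuple[str, str, str], GermlineSegment]
) -> str:
    v = segments[(rearr.chain, "V", rearr.v_name)]
    j = segments[(rearr.chain, "J", rearr.j_name)]
    return ADAPTER + v.sequence + rearr.junction_insert + j.sequence + CONSTANT_STUBS[rearr.chain]


def simulate_repertoire_reads(
    spec: RepertoireSimSpec,
    reference: Sequence[GermlineSegment] | None = None,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Simulate amplicon reads from a clone mixture.

    Each read picks a clone from the mixture, then one of its two chains
    with equal probability, and copies adapter + V + insert + J + constant
    stub with per-base substitution errors. Returns FASTQ-ready records
    (ids ``read<N>|clone<K>|<chain>`` carry the truth label) and a truth
    table with the expected per-chain clonotype frequencies (columns clone,
    chain, v, j, cdr3_nt, frequency).
    """
    reference = list(reference) if reference is not None else builtin_germline()
    by_key = {(s.chain, s.segment_type, s.name): s for s in reference}
    rng = np.random.default_rng(spec.seed)

    truth_rows = []
    for ci, (pair, freq) in enumerate(zip(spec.clones, spec.frequencies), start=1):
        for rearr in (pair.tra, pair.trb):
            v = by_key[(rearr.chain, "V", rearr.v_name)]
            j = by_key[(rearr.chain, "J", rearr.j_name)]
            truth_rows.append({
                "clone": f"clone{ci}",
                "chain": rearr.chain,
                "v": rearr.v_name,
                "j": rearr.j_name,
                "cdr3_nt": truth_cdr3(v, j, rearr.junction_insert),
                "frequency": freq,
            })
    truth = pd.DataFrame(truth_rows, columns=["clone", "chain", "v", "j", "cdr3_nt", "frequency"])

    templates = [
        (_clean_read(pair.tra, by_key), _clean_read(pair.trb, by_key))
        for pair in spec.clones
    ]
    clone_draws = rng.choice(len(spec.clones), size=spec.n_reads, p=spec.frequencies)
    chain_draws = rng.integers(0, 2, size=spec.n_reads)

    records: list[SeqRecord] = []
    for i in range(spec.n_reads):
        ci = int(clone_draws[i])
        chain = ("TRA", "TRB")[int(chain_draws[i])]
        template = templates[ci][int(chain_draws[i])]
        seq = list(template)
        if spec.error_rate > 0:
            err_mask = rng.random(len(seq)) < spec.error_rate
            for pos in np.flatnonzero(err_mask):
                choices = [b for b in BASES if b != seq[pos]]
                seq[pos] = choices[int(rng.integers(0, 3))]
        rec = SeqRecord(
            Seq("".join(seq)),
            id=f"read{i + 1}|clone{ci + 1}|{chain}",
            description="",
        )
        rec.letter_annotations["phred_quality"] = [35] * len(seq)
        records.append(rec)
    return records, truth


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(records), str(path), "fastq")


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(records), str(path), "fasta")
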