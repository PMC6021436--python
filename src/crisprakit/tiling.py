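"""PAM-tiling synthetic promoter generation with constraint filters.

The generator builds candidate promoter arrays by repeating the base unit
5′-NNNCCNNNGG-3′, which guarantees an NGG PAM every 10 nucleotides on each
strand: the fixed GG provides a + strand PAM in every repeat and the fixed CC
a − strand PAM. N positions are sampled so the *whole-sequence* GC fraction
matches a target (default 0.508, the E. coli genomic GC content), accounting
for the 4 fixed G/C bases per unit.

Candidates are then screened by three filters applied in a fixed order:

1. homopolymer — discard any sequence with ≥4 consecutive identical bases
   (runs of 3 are allowed);
2. transcription-factor binding sites — discard sequences containing any
   listed site (e.g. a RegulonDB export) as an exact substring on either
   strand;
3. genome homology — discard sequences sharing any exact k-mer (default
   k=15) with a background genome on either strand.

The first candidate passing all filters is returned; the "arbitrary choice"
among passers is made reproducible as first-passing-index under the seed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .seqcore import NucSequence, normalize_bases, reverse_complement

DEFAULT_BASE_UNIT = "NNNCCNNNGG"
FILTER_ORDER = ("homopolymer", "tf_sites", "genome_homology")


@dataclass(frozen=True)
class DesignParams:
    """Generation and filtering parameters for a tiling-array design run.

    Defaults reproduce the published generation scale: 10000 candidates of
    500 nt from the NNNCCNNNGG base unit, GC-matched to the E. coli genome,
    homopolymer runs capped at 3, and a 170 nt fragment selected from the
    chosen array.
    """

    base_unit: str = DEFAULT_BASE_UNIT
    candidate_length: int = 500
    n_candidates: int = 10000
    gc_target: float = 0.508
    max_homopolymer_run: int = 3
    fragment_length: int = 170
    rng_seed: int = 0
    tf_sites_path: Optional[str] = None
    genome_path: Optional[str] = None
    kmer_k: int = 15

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError(f"gc_target must be in (0, 1), got {self.gc_target}")
        if self.fragment_length > self.candidate_length:
            raise ValueError("fragment_length must not exceed candidate_length")
        if self.candidate_length <= 0 or self.n_candidates <= 0:
            raise ValueError("candidate_length and n_candidates must be positive")


@dataclass(frozen=True)
class FilterResult:
    """Verdict of one constraint filter, with enough detail to explain a rejection."""

    name: str
    passed: bool
    detail: str = ""
    #: filter-specific payload: offending interval, matched site ids, or
    #: (shared k-mer count, first shared k-mer)
    data: object = None

    def __bool__(self) -> bool:
        return self.passed


@dataclass(frozen=True)
class TilingDesign:
    """A generated array with its provenance: params, seed, filter verdicts, fragment."""

    seq: NucSequence
    params: DesignParams
    filters_passed: dict
    fragment: Optional[NucSequence]
    seed_used: int
    candidate_index: int
    rejection_reason: Optional[str] = None


@dataclass(frozen=True)
class DesignRun:
    """Result of design_array: the chosen design plus per-filter attrition counts."""

    design: TilingDesign
    attrition: dict
    n_evaluated: int


def n_position_probabilities(base_unit: str, gc_target: float) -> dict[str, float]:
    """Per-N sampling probabilities so the whole-unit expected GC equals gc_target.

    The fixed G/C bases of the unit set a floor on achievable GC: for
    NNNCCNNNGG (4 fixed G/C in 10 nt) the target must exceed 0.4. The G/C
    mass is split equally between G and C, and A/T share the remainder.
    """
    unit = base_unit.upper()
    n_count = unit.count("N")
    if n_count == 0:
        raise ValueError("base unit has no N positions to sample")
    fixed_gc = sum(1 for b in unit if b in "GC")
    p_gc = (len(unit) * gc_target - fixed_gc) / n_count
    if p_gc < 0:
        raise ValueError(
            f"gc_target {gc_target} is below the fixed-base floor "
            f"{fixed_gc}/{len(unit)} = {fixed_gc / len(unit)} of unit {base_unit!r}"
        )
    if p_gc > 1:
        raise ValueError(f"gc_target {gc_target} infeasible: would need per-N GC {p_gc} > 1")
    return {
        "A": (1 - p_gc) / 2,
        "C": p_gc / 2,
        "G": p_gc / 2,
        "T": (1 - p_gc) / 2,
    }


def fill_base_units(
    params: DesignParams, rng: np.random.Generator, seq_id: str = "candidate"
) -> NucSequence:
    """Sample one candidate: tiled base units with N positions drawn i.i.d.

    Fixed pattern positions (the C/C and G/G of the default unit) are
    preserved exactly; each N is drawn from the GC-calibrated distribution.
    If candidate_length is not a multiple of the unit length it is truncated
    to the largest multiple, with a warning.
    """
    unit = params.base_unit.upper()
    n_units, remainder = divmod(params.candidate_length, len(unit))
    if remainder:
        warnings.warn(
            f"candidate_length {params.candidate_length} is not a multiple of the "
            f"{len(unit)} nt base unit; truncating to {n_units * len(unit)} nt"
        )
    if n_units == 0:
        raise ValueError("candidate_length shorter than one base unit")
    probs = n_position_probabilities(unit, params.gc_target)
    arr = np.tile(np.array(list(unit)), n_units)
    mask = arr == "N"
    arr[mask] = rng.choice(
        np.array(list("ACGT")),
        size=int(mask.sum()),
        p=[probs[b] for b in "ACGT"],
    )
    return NucSequence("".join(arr), seq_id)


def homopolymer_filter(seq: NucSequence, max_run: int = 3) -> FilterResult:
    """Fail iff any single-base run exceeds max_run; reports the first offender."""
    match = re.search(rf"([ACGTN])\1{{{max_run},}}", seq.bases)
    if match is None:
        return FilterResult("homopolymer", True)
    return FilterResult(
        "homopolymer",
        False,
        detail=(
            f"run of {match.end() - match.start()} × {match.group(1)!r} "
            f"at [{match.start()}, {match.end()})"
        ),
        data=(match.start(), match.end()),
    )


def read_tf_sites(path) -> list[tuple[str, str]]:
    """Read a tab-delimited (site_id, site_sequence) list, validating sequences."""
    sites = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected site_id<TAB>sequence")
        site_id, raw = fields[0], fields[1]
        try:
            sites.append((site_id, normalize_bases(raw, site_id)))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: site {site_id!r}: {exc}") from exc
    return sites


def tf_site_filter(seq: NucSequence, site_list: Sequence[tuple[str, str]]) -> FilterResult:
    """Fail iff any listed site occurs as an exact substring of seq or its reverse complement."""
    matched = [
        site_id
        for site_id, site_seq in site_list
        if site_seq in seq.bases or reverse_complement(site_seq) in seq.bases
    ]
    if not matched:
        return FilterResult("tf_sites", True)
    return FilterResult(
        "tf_sites",
        False,
        detail=f"contains TF binding site(s): {', '.join(matched)}",
        data=matched,
    )


def _kmer_set(bases: str, k: int) -> set[str]:
    return {bases[i : i + k] for i in range(len(bases) - k + 1)}


def genome_homology_filter(
    seq: NucSequence, genome: Sequence[NucSequence], k: int = 15
) -> FilterResult:
    """Fail iff seq shares any exact k-mer with the genome on either strand.

    Counts the number of query positions whose k-mer occurs in the genome
    (so a self-match reports len(seq) − k + 1 shared k-mers) and names the
    first one.
    """
    if k > len(seq):
        raise ValueError(f"k={k} exceeds query length {len(seq)}")
    genome_kmers: set[str] = set()
    for chrom in genome:
        genome_kmers |= _kmer_set(chrom.bases, k)
        genome_kmers |= _kmer_set(reverse_complement(chrom.bases), k)
    shared_positions = [
        i for i in range(len(seq) - k + 1) if seq.bases[i : i + k] in genome_kmers
    ]
    if not shared_positions:
        return FilterResult("genome_homology", True, data=(0, None))
    first = seq.bases[shared_positions[0] : shared_positions[0] + k]
    return FilterResult(
        "genome_homology",
        False,
        detail=f"{len(shared_positions)} query position(s) share a {k}-mer "
        f"with the genome; first: {first}",
        data=(len(shared_positions), first),
    )


def select_fragment(
    seq: NucSequence, fragment_length: int, placement="three_prime"
) -> NucSequence:
    """Slice the fragment that will be placed upstream of the minimal promoter.

    ``three_prime`` (default) takes the promoter-proximal end of the array,
    ``five_prime`` the other end; an integer placement is a 0-based offset.
    """
    if fragment_length > len(seq):
        raise ValueError(
            f"fragment_length {fragment_length} exceeds sequence length {len(seq)}"
        )
    if placement == "three_prime":
        offset = len(seq) - fragment_length
    elif placement == "five_prime":
        offset = 0
    elif isinstance(placement, int):
        offset = placement
        if not 0 <= offset <= len(seq) - fragment_length:
            raise ValueError(f"offset {offset} out of bounds for fragment of {fragment_length}")
    else:
        raise ValueError(f"placement must be 'three_prime', 'five_prime' or an offset")
    return NucSequence(
        seq.bases[offset : offset + fragment_length],
        f"{seq.id}_frag{offset}" if seq.id else f"frag{offset}",
    )


class DesignExhaustedError(RuntimeError):
    """All candidates were rejected; carries the per-filter attrition table."""

    def __init__(self, attrition: dict, n_evaluated: int):
        self.attrition = attrition
        self.n_evaluated = n_evaluated
        table = ", ".join(f"{name}: {count}" for name, count in attrition.items())
        super().__init__(
            f"all {n_evaluated} candidates rejected (attrition — {table}); "
            "relax filters or increase n_candidates"
        )


def design_array(
    params: DesignParams,
    tf_sites: Optional[Sequence[tuple[str, str]]] = None,
    genome: Optional[Sequence[NucSequence]] = None,
) -> DesignRun:
    """Generate seeded candidates and return the first one passing every filter.

    Filters run in the fixed order homopolymer → tf_sites → genome_homology;
    each rejection is attributed to the first filter that failed. TF sites
    and genome default to the paths in ``params`` when not passed directly.
    The run is fully determined by (seed, params): repeating it yields a
    byte-identical design.
    """
    if tf_sites is None and params.tf_sites_path:
        tf_sites = read_tf_sites(params.tf_sites_path)
    if genome is None and params.genome_path:
        from .seqcore import read_fasta

        genome = read_fasta(params.genome_path)

    rng = np.random.default_rng(params.rng_seed)
    attrition = {name: 0 for name in FILTER_ORDER}

    for index in range(params.n_candidates):
        candidate = fill_base_units(params, rng, seq_id=f"candidate{index}")
        verdicts = {}

        result = homopolymer_filter(candidate, params.max_homopolymer_run)
        verdicts["homopolymer"] = result.passed
        if result.passed and tf_sites is not None:
            result = tf_site_filter(candidate, tf_sites)
            verdicts["tf_sites"] = result.passed
        if result.passed and genome is not None:
            result = genome_homology_filter(candidate, genome, params.kmer_k)
            verdicts["genome_homology"] = result.passed

        if not result.passed:
            attrition[result.name] += 1
            continue

        fragment = select_fragment(candidate, params.fragment_length)
        design = TilingDesign(
            seq=candidate,
            params=params,
            filters_passed=verdicts,
            fragment=fragment,
            seed_used=params.rng_seed,
            candidate_index=index,
        )
        return DesignRun(design=design, attrition=attrition, n_evaluated=index + 1)

    raise DesignExhaustedError(attrition, params.n_candidates)


def anchored_pam_positions(seq: NucSequence, base_unit: str = DEFAULT_BASE_UNIT):
    """Start positions of the base-unit-anchored PAMs on each strand.

    For the default unit the + strand PAM (NGG) starts at offset 7 of each
    repeat and the − strand PAM (CCN on the + strand) at offset 3. Returns
    ``(plus_starts, minus_starts)`` for repeats where the expected fixed
    bases are actually present (always, for sequences built from the unit).
    """
    unit = base_unit.upper()
    period = len(unit)
    gg = unit.rfind("GG")
    cc = unit.find("CC")
    if gg < 1 or cc < 0:
        raise ValueError(f"base unit {base_unit!r} lacks the fixed GG/CC PAM anchors")
    plus, minus = [], []
    for rep_start in range(0, len(seq) - period + 1, period):
        p = rep_start + gg - 1  # NGG starts one base before the fixed GG
        if seq.bases[p + 1 : p + 3] == "GG":
            plus.append(p)
        m = rep_start + cc  # CCN on the + strand is the − strand NGG
        if seq.bases[m : m + 2] == "CC":
            minus.append(m)
    return plus, minus
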