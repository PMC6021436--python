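"""Deterministic synthetic inputs: promoters with planted target sites, toy genomes, TF-site lists.

Everything downstream of sequence I/O is testable against exact ground truth
generated here: a promoter background is built PAM-free throughout the
scanned upstream window (no GG or CC dinucleotide can exist there, hence no
NGG on either strand), then protospacer+PAM cassettes are planted so that
the configured distance anchor lands at exactly the requested number of
bases upstream of the TSS on the requested strand class. The construction
is verified internally with the scanner, so the returned expected-site list
is a true oracle. All outputs are byte-reproducible from (seed, spec).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import scanner
from .scanner import _ANCHOR_OFFSETS, DEFAULT_ANCHOR, NON_TEMPLATE, TEMPLATE, TargetSite
from .seqcore import (
    FORWARD,
    REVERSE,
    GenomicInterval,
    NucSequence,
    PromoterRecord,
    reverse_complement,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for synthetic fixture generation.

    ``planted_sites`` lists (bases_upstream, strand_class) pairs;
    ``decoy_density`` is the per-base rate of decoy PAMs planted downstream
    of the TSS (they exercise the downstream-flagging path and never affect
    upstream ground truth). ``tss_offset`` is the 0-based TSS index.
    """

    rng_seed: int = 0
    promoter_length: int = 220
    tss_offset: int = 180
    planted_sites: tuple = ((91, NON_TEMPLATE),)
    decoy_density: float = 0.0
    tf_decoys: int = 8
    tf_site_length: int = 12
    genome_length: int = 2000
    gene_strand: str = FORWARD

    def __post_init__(self) -> None:
        if not 0 <= self.tss_offset < self.promoter_length:
            raise ValueError("tss_offset must lie within the promoter")
        if self.gene_strand not in (FORWARD, REVERSE):
            raise ValueError("gene_strand must be 'forward' or 'reverse'")


def _draw_no_gg_cc(rng: np.random.Generator, n: int, prev: str = "") -> list[str]:
    """Sequence of n bases with no GG or CC dinucleotide (given the preceding base)."""
    out = []
    for _ in range(n):
        if prev in "GC":
            choices = [b for b in "ACGT" if b != prev]
        else:
            choices = list("ACGT")
        prev = choices[int(rng.integers(len(choices)))]
        out.append(prev)
    return out


def _plant_cassette(d: int, strand_class: str, tss: int, anchor: str, rng):
    """Build one protospacer+PAM cassette for a forward gene at upstream distance d.

    Returns (interval_start, plus_strand_23mer, site_strand, protospacer, pam).
    """
    site_strand = "+" if strand_class == NON_TEMPLATE else "-"
    offset = _ANCHOR_OFFSETS[site_strand][anchor]
    start = tss - d - offset
    if site_strand == "+":
        proto = "".join(_draw_no_gg_cc(rng, 20))
        return start, proto + "AGG", "+", proto, "AGG"
    proto_plus = "".join(_draw_no_gg_cc(rng, 20))
    return start, "CCT" + proto_plus, "-", reverse_complement(proto_plus), "AGG"


def make_promoter_with_sites(
    spec: FixtureSpec, anchor: str = DEFAULT_ANCHOR, seq_id: str = "fixture_promoter"
):
    """Promoter with planted target sites and the exact expected scanner output.

    Returns ``(PromoterRecord, expected_sites)`` where expected_sites are the
    planted sites annotated with distance and strand class, sorted the way
    the scanner sorts. Raises if planted sites collide or do not fit, and
    verifies the construction against the scanner before returning.
    """
    rng = np.random.default_rng([0, spec.rng_seed])  # substream distinct per generator
    length, tss = spec.promoter_length, spec.tss_offset

    # mirror trick: build in a forward-gene frame, flip at the end if needed
    if spec.gene_strand == REVERSE:
        build_tss = length - 1 - tss
    else:
        build_tss = tss

    # window (all upstream positions) + margin kept free of GG/CC dinucleotides
    guard = min(length, build_tss + 25)
    seq = _draw_no_gg_cc(rng, guard)
    for _ in range(length - guard):
        seq.append(str(_BASES[int(rng.integers(4))]))

    planted = []  # (start, end, site_strand, proto, pam, distance, strand_class)
    for d, strand_class in spec.planted_sites:
        if strand_class not in (NON_TEMPLATE, TEMPLATE):
            raise ValueError(f"unknown strand class {strand_class!r}")
        if d < 1:
            raise ValueError(f"planted distances must be >= 1, got {d}")
        start, cassette, site_strand, proto, pam = _plant_cassette(
            d, strand_class, build_tss, anchor, rng
        )
        end = start + scanner.SITE_LEN
        if start < 0 or end > length:
            raise ValueError(
                f"site at distance {d} ({strand_class}) does not fit: "
                f"interval [{start}, {end}) outside promoter of length {length}"
            )
        for p_start, p_end, *_ in planted:
            if start < p_end and p_start < end:
                raise ValueError(
                    f"planted sites collide: [{start}, {end}) overlaps [{p_start}, {p_end})"
                )
        seq[start:end] = list(cassette)
        planted.append((start, end, site_strand, proto, pam, d, strand_class))

    _repair_junctions(seq, planted, guard)

    # decoy PAMs downstream of the TSS (scored 0, flagged downstream)
    n_decoys = int(spec.decoy_density * max(0, length - guard))
    for _ in range(n_decoys):
        pos = int(rng.integers(guard, max(guard + 1, length - 2)))
        seq[pos : pos + 2] = ["G", "G"]

    bases = "".join(seq)
    if spec.gene_strand == REVERSE:
        bases = reverse_complement(bases)

    promoter = PromoterRecord(NucSequence(bases, seq_id), tss, spec.gene_strand)

    expected = []
    for start, end, site_strand, proto, pam, d, strand_class in planted:
        if spec.gene_strand == REVERSE:
            start, end = length - end, length - start
            site_strand = "-" if site_strand == "+" else "+"
        site = TargetSite(
            protospacer=proto,
            pam=pam,
            interval=GenomicInterval(seq_id, start, end, site_strand),
            site_strand=site_strand,
            strand_class=strand_class,
            tss_distance=d,
        )
        expected.append(site)
    expected.sort(key=lambda s: (s.tss_distance, 0 if s.site_strand == "+" else 1))

    _verify_against_scanner(promoter, expected, anchor)
    return promoter, expected


def _repair_junctions(seq: list, planted: list, guard: int) -> None:
    """Destroy unintended GG/CC dinucleotides created at plant boundaries.

    Within the guarded window the background has none and cassettes are
    internally clean except for their intended PAM dinucleotide, so any
    stray GG/CC must straddle a plant edge; the background member is mutated
    to A/T, which can never form a new GG/CC.
    """
    intended = set()
    covered = set()
    for start, end, site_strand, *_ in planted:
        covered.update(range(start, end))
        if site_strand == "+":
            intended.add(start + 21)  # the GG of ...NGG
        else:
            intended.add(start)  # the CC of CCN...
    for i in range(guard - 1):
        pair = seq[i] + seq[i + 1]
        if pair not in ("GG", "CC") or i in intended:
            continue
        if i not in covered:
            seq[i] = "A" if seq[i] == "G" else "T"
        elif i + 1 not in covered:
            seq[i + 1] = "A" if seq[i + 1] == "G" else "T"
        else:
            raise ValueError(
                "planted sites abut in a way that creates an unintended PAM; "
                "space the planted distances further apart"
            )


def _verify_against_scanner(promoter, expected, anchor) -> None:
    found = [
        s for s in scanner.find_pam_sites(promoter, anchor=anchor) if s.tss_distance >= 1
    ]
    got = {(s.interval.start, s.site_strand) for s in found}
    want = {(s.interval.start, s.site_strand) for s in expected}
    if got != want:
        raise RuntimeError(
            f"fixture construction inconsistent with scanner: planted {sorted(want)}, "
            f"scanner found {sorted(got)}"
        )


def make_toy_genome(
    spec: FixtureSpec, embed: Optional[str] = None, seq_id: str = "toy_genome"
):
    """Random genome sequence, optionally with one planted k-mer at a recorded offset.

    Returns ``(NucSequence, embed_offset)``; the offset is None when nothing
    was embedded.
    """
    rng = np.random.default_rng([2, spec.rng_seed])
    bases = list(_BASES[rng.integers(4, size=spec.genome_length)])
    offset = None
    if embed is not None:
        if len(embed) > spec.genome_length:
            raise ValueError("embedded k-mer longer than the genome")
        offset = int(rng.integers(0, spec.genome_length - len(embed) + 1))
        bases[offset : offset + len(embed)] = list(embed.upper())
    return NucSequence("".join(bases), seq_id), offset


def make_tf_site_list(
    spec: FixtureSpec,
    include_from: Optional[NucSequence] = None,
    copy_positive: bool = False,
) -> list[tuple[str, str]]:
    """Decoy TF binding sites guaranteed absent from a sequence, optionally plus one real one.

    Decoys are random ``tf_site_length``-mers rejection-sampled so that
    neither they nor their reverse complements occur in ``include_from``.
    With ``copy_positive`` a substring of ``include_from`` is appended as a
    positive control (id "positive_control").
    """
    rng = np.random.default_rng([1, spec.rng_seed])
    k = spec.tf_site_length
    sites: list[tuple[str, str]] = []
    attempts = 0
    while len(sites) < spec.tf_decoys:
        attempts += 1
        if attempts > 1000 * max(1, spec.tf_decoys):
            raise RuntimeError("could not sample decoys absent from the sequence")
        cand = "".join(_BASES[rng.integers(4, size=k)])
        if include_from is not None and (
            cand in include_from.bases
            or reverse_complement(cand) in include_from.bases
        ):
            continue
        sites.append((f"decoy{len(sites)}", cand))
    if copy_positive:
        if include_from is None or len(include_from) < k:
            raise ValueError("copy_positive requires include_from of length >= site length")
        start = int(rng.integers(0, len(include_from) - k + 1))
        sites.append(("positive_control", include_from.bases[start : start + k]))
    return sites


def write_tf_sites(sites: Sequence[tuple[str, str]], path) -> None:
    """Write a (site_id, sequence) list in the tab-delimited dialect the filter reads."""
    Path(path).write_text("".join(f"{sid}\t{seq}\n" for sid, seq in sites))
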