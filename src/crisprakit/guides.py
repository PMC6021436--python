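"""Assembly and validation of guide RNAs for the scaffold dialects used in bacterial CRISPRa.

A scaffold RNA (scRNA) is a Cas9 guide extended with aptamer hairpins (MS2 or
PP7) that recruit coat-protein–activator fusions (MCP-SoxS, PCP-SoxS, ...).
The variants modelled here:

* ``gRNA`` — plain guide, no recruitment hairpin (CRISPRi use).
* ``scRNA_original`` — MS2 hairpin appended 3′ of the tracr terminator hairpin.
* ``scRNA.b1`` — terminator hairpin removed, 3′ MS2 retained (the optimized
  bacterial design; removing the terminator raises full-length scRNA levels).
* ``scRNA.b2`` — functionally equivalent to b1, differing by a single base at
  the 5′ end of the (former) terminator hairpin junction.
* ``scRNA_2xMS2`` — two MS2 hairpins.
* ``scRNA_PP7_b1`` — b1 architecture with a PP7 hairpin instead of MS2.
* ``sgRNA2.0`` — MS2 hairpins embedded inside internal guide hairpins; highly
  effective in eukaryotes but shows no significant activity in E. coli, so
  validation attaches a warning.

The templates shipped here are **synthetic stubs**: they combine the
canonical S. pyogenes guide scaffold with wild-type MS2/PP7 aptamer sequences
and preserve the structural relationships above (hairpin counts, terminator
presence, the b1/b2 single-base difference), but they are not the exact
published construct sequences, which are distributed with the original
reagents. Supply real sequences via a YAML scaffold config for production
designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .scanner import TargetSite

SPACER_PLACEHOLDER = "[SPACER]"
SPACER_LEN = 20

_RNA_BASES = frozenset("ACGU")
_DNA_TO_RNA = str.maketrans("T", "U")
_RNA_TO_DNA = str.maketrans("U", "T")

MS2_HAIRPIN = "ACAUGAGGAUCACCCAUGU"  # wild-type MS2 aptamer
PP7_HAIRPIN = "GGAGCAGACGAUAUGGCGUCGCUCC"  # wild-type PP7 aptamer
# canonical S. pyogenes guide scaffold, split at the tracr terminator hairpin
_CORE = "GUUUUAGAGCUAGAAAUAGCAAGUUAAAAUAAGGCUAGUCCGUUAUCAACUUGAAAAAGUG"
_TERMINATOR = "GCACCGAGUCGGUGCUUUUUU"


@dataclass(frozen=True)
class ScaffoldTemplate:
    """A guide scaffold with exactly one spacer placeholder and hairpin annotations.

    ``sequence`` is RNA-alphabet (plus the placeholder token); annotation
    intervals are 0-based half-open coordinates on the template string and
    are shifted automatically when the placeholder is replaced by a 20-nt
    spacer.
    """

    name: str
    sequence: str
    hairpin_annotations: tuple = ()

    def __post_init__(self) -> None:
        if self.sequence.count(SPACER_PLACEHOLDER) != 1:
            raise ValueError(
                f"template {self.name!r} must contain exactly one {SPACER_PLACEHOLDER}"
            )
        body = self.sequence.replace(SPACER_PLACEHOLDER, "")
        bad = set(body) - _RNA_BASES
        if bad:
            raise ValueError(f"template {self.name!r}: non-RNA characters {sorted(bad)}")
        for label, (start, end) in self.hairpin_annotations:
            if not 0 <= start < end <= len(self.sequence):
                raise ValueError(
                    f"template {self.name!r}: annotation {label!r} interval "
                    f"[{start}, {end}) outside template"
                )


def _ann(seq_parts):
    """Build (sequence, annotations) from labelled parts; None labels are unannotated."""
    sequence = ""
    annotations = []
    for label, part in seq_parts:
        if label is not None:
            annotations.append((label, (len(sequence), len(sequence) + len(part))))
        sequence += part
    return sequence, tuple(annotations)


def builtin_templates() -> dict[str, ScaffoldTemplate]:
    """The shipped synthetic stub templates, keyed by variant name."""
    templates = {}

    def add(name, parts):
        seq, ann = _ann(parts)
        templates[name] = ScaffoldTemplate(name, seq, ann)

    spacer = (None, SPACER_PLACEHOLDER)
    add("gRNA", [spacer, (None, _CORE), ("tracr-terminator", _TERMINATOR)])
    add(
        "scRNA_original",
        [spacer, (None, _CORE), ("tracr-terminator", _TERMINATOR), ("MS2", MS2_HAIRPIN)],
    )
    add("scRNA.b1", [spacer, (None, _CORE), ("MS2", MS2_HAIRPIN)])
    # b2 differs from b1 by one base at the 5' junction where the terminator
    # hairpin attaches in the terminator-bearing designs (core final G -> A)
    core_b2 = _CORE[:-1] + "A"
    add("scRNA.b2", [spacer, (None, core_b2), ("MS2", MS2_HAIRPIN)])
    add(
        "scRNA_2xMS2",
        [spacer, (None, _CORE), ("MS2", MS2_HAIRPIN), (None, "GC"), ("MS2", MS2_HAIRPIN)],
    )
    add("scRNA_PP7_b1", [spacer, (None, _CORE), ("PP7", PP7_HAIRPIN)])
    # sgRNA 2.0: MS2 hairpins embedded within internal scaffold hairpins
    add(
        "sgRNA2.0",
        [
            spacer,
            (None, _CORE[:22]),
            ("MS2", MS2_HAIRPIN),
            (None, _CORE[22:48]),
            ("MS2", MS2_HAIRPIN),
            (None, _CORE[48:]),
            ("tracr-terminator", _TERMINATOR),
        ],
    )
    return templates


#: Hairpin complements each variant is expected to carry, checked by validate_guide.
EXPECTED_HAIRPINS = {
    "gRNA": {"MS2": 0, "PP7": 0},
    "scRNA_original": {"MS2": 1, "PP7": 0},
    "scRNA.b1": {"MS2": 1, "PP7": 0},
    "scRNA.b2": {"MS2": 1, "PP7": 0},
    "scRNA_2xMS2": {"MS2": 2, "PP7": 0},
    "scRNA_PP7_b1": {"MS2": 0, "PP7": 1},
    "sgRNA2.0": {"MS2": 2, "PP7": 0},
}

#: Variants with documented lack of efficacy in E. coli.
INEFFECTIVE_IN_ECOLI = {
    "sgRNA2.0": "no significant activity observed in E. coli at any target site"
}


def load_scaffold_config(path) -> dict[str, ScaffoldTemplate]:
    """Load scaffold templates from YAML: name -> {sequence, hairpins: [[label, start, end]]}."""
    raw = yaml.safe_load(open(path))
    templates = {}
    for name, entry in raw.items():
        ann = tuple(
            (label, (int(start), int(end)))
            for label, start, end in entry.get("hairpins", [])
        )
        templates[name] = ScaffoldTemplate(name, entry["sequence"].upper(), ann)
    return templates


@dataclass(frozen=True)
class GuideConstruct:
    """An assembled guide: 20-nt DNA spacer substituted into a scaffold template."""

    spacer: str
    scaffold: str
    full_sequence: str  # RNA form
    hairpin_annotations: tuple
    target_site_ref: Optional[TargetSite] = None

    @property
    def dna(self) -> str:
        """DNA form for cloning (U -> T)."""
        return self.full_sequence.translate(_RNA_TO_DNA)


def assemble_guide(
    spacer: str,
    template: ScaffoldTemplate,
    target_site_ref: Optional[TargetSite] = None,
) -> GuideConstruct:
    """Substitute a DNA spacer (as transcribed, T->U) into the template.

    The spacer must be 20 nt of A/C/G/T and, when a target site is attached,
    identical to its protospacer. Annotation coordinates downstream of the
    placeholder shift by 20 − len(placeholder).
    """
    spacer = spacer.upper()
    if len(spacer) != SPACER_LEN:
        raise ValueError(f"spacer must be {SPACER_LEN} nt, got {len(spacer)}")
    if set(spacer) - set("ACGT"):
        raise ValueError(f"spacer must be DNA over A/C/G/T, got {spacer!r}")
    pidx = template.sequence.index(SPACER_PLACEHOLDER)
    shift = SPACER_LEN - len(SPACER_PLACEHOLDER)
    full = template.sequence.replace(SPACER_PLACEHOLDER, spacer.translate(_DNA_TO_RNA))
    annotations = tuple(
        (label, (start + shift, end + shift)) if start >= pidx + len(SPACER_PLACEHOLDER)
        else (label, (start, end))
        for label, (start, end) in template.hairpin_annotations
    )
    return GuideConstruct(
        spacer=spacer,
        scaffold=template.name,
        full_sequence=full,
        hairpin_annotations=annotations,
        target_site_ref=target_site_ref,
    )


@dataclass(frozen=True)
class DiffReport:
    """Positional comparison of two constructs.

    For equal lengths, ``differing_positions`` is the full positional diff.
    For unequal lengths the common prefix is compared and ``tail_start``
    marks where the extra 3′ sequence of the longer construct begins.
    """

    length_a: int
    length_b: int
    differing_positions: tuple
    tail_start: Optional[int] = None

    @property
    def identical(self) -> bool:
        return self.length_a == self.length_b and not self.differing_positions


def diff_constructs(a: GuideConstruct, b: GuideConstruct) -> DiffReport:
    """Compare two assembled constructs position by position (no alignment)."""
    sa, sb = a.full_sequence, b.full_sequence
    n = min(len(sa), len(sb))
    diffs = tuple(i for i in range(n) if sa[i] != sb[i])
    tail = n if len(sa) != len(sb) else None
    return DiffReport(len(sa), len(sb), diffs, tail)


@dataclass(frozen=True)
class ValidationReport:
    passed: bool
    checks: tuple  # (check_name, ok, message)
    warnings: tuple = ()


def validate_guide(construct: GuideConstruct) -> ValidationReport:
    """Pure structural validation of an assembled guide.

    Checks spacer/protospacer identity when a target site is attached and
    that the variant carries its expected hairpin complement; attaches an
    efficacy warning for variants documented not to work in E. coli.
    """
    checks = []
    warns = []

    if construct.target_site_ref is not None:
        ok = construct.spacer == construct.target_site_ref.protospacer
        checks.append(
            (
                "spacer_matches_protospacer",
                ok,
                "" if ok else f"spacer {construct.spacer} != protospacer "
                f"{construct.target_site_ref.protospacer}",
            )
        )
        if not ok:
            raise ValueError(
                "spacer does not match the referenced target site's protospacer: "
                f"{construct.spacer} vs {construct.target_site_ref.protospacer}"
            )

    expected = EXPECTED_HAIRPINS.get(construct.scaffold)
    if expected is not None:
        counts = {"MS2": 0, "PP7": 0}
        for label, _ in construct.hairpin_annotations:
            if label in counts:
                counts[label] += 1
        for hairpin, want in expected.items():
            ok = counts[hairpin] == want
            checks.append(
                (
                    f"{hairpin}_hairpin_count",
                    ok,
                    "" if ok else f"expected {want} {hairpin} hairpin(s), found {counts[hairpin]}",
                )
            )
    else:
        warns.append(f"unknown scaffold variant {construct.scaffold!r}; hairpin counts not checked")

    if construct.scaffold in INEFFECTIVE_IN_ECOLI:
        msg = f"{construct.scaffold}: {INEFFECTIVE_IN_ECOLI[construct.scaffold]}"
        warns.append(msg)
        warnings.warn(msg)

    return ValidationReport(
        passed=all(ok for _, ok, _ in checks),
        checks=tuple(checks),
        warnings=tuple(warns),
    )
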