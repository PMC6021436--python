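"""Quantification formulas for CRISPRa characterization assays.

Covers the arithmetic behind the standard readouts: β-galactosidase Miller
units, ΔΔCt relative qPCR quantification against a reference gene (16S rRNA
in bacteria), OD-normalized plate-reader fluorescence, fermentation product
yield against initial substrate, and the peptide-linker / B-DNA geometry
used to reason about how far a recruited activator can reach between
PAM-tiled target sites (3.8 Å per residue for a flexible linker, 3.3 Å rise
per base pair).
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class MillerAssay:
    """One β-galactosidase assay reading.

    ``culture_volume`` is the assayed culture volume in mL (0.02 mL in the
    standard microplate protocol); ``time`` is the reaction time in minutes.
    """

    a420: float
    od600: float
    culture_volume: float = 0.02
    time: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a420", "od600", "culture_volume", "time"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and > 0, got {value}")


@dataclass(frozen=True)
class CtQuad:
    """The four Ct values of one ΔΔCt comparison (target/reference × test/control)."""

    ct_target_test: float
    ct_ref_test: float
    ct_target_control: float
    ct_ref_control: float

    def __post_init__(self) -> None:
        for name in ("ct_target_test", "ct_ref_test", "ct_target_control", "ct_ref_control"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class GeometryParams:
    """Contour-length constants: Å per peptide residue and Å rise per DNA bp."""

    aa_contour: float = 3.8
    bp_rise: float = 3.3

    def __post_init__(self) -> None:
        if self.aa_contour <= 0 or self.bp_rise <= 0:
            raise ValueError("geometry constants must be positive")


def miller_units(assay: MillerAssay) -> float:
    """Miller units = 1000 · A420 / (OD600 · volume[mL] · time[min])."""
    return 1000.0 * assay.a420 / (assay.od600 * assay.culture_volume * assay.time)


def ddct_fold_change(q: CtQuad, efficiency: float = 2.0) -> float:
    """Relative expression by the ΔΔCt method: efficiency^(−ΔΔCt).

    ΔCt = Ct(target) − Ct(reference) within each condition; ΔΔCt =
    ΔCt(test) − ΔCt(control). The classic method assumes perfect doubling
    per cycle (efficiency 2); an amplification-efficiency parameter is
    exposed for generality.
    """
    if efficiency <= 1.0:
        raise ValueError(f"amplification efficiency must exceed 1, got {efficiency}")
    dct_test = q.ct_target_test - q.ct_ref_test
    dct_control = q.ct_target_control - q.ct_ref_control
    ddct = dct_test - dct_control
    return efficiency ** (-ddct)


def od_normalized_fluorescence(fluor: float, od600: float) -> float:
    """Plate-reader fluorescence normalized by cell density (fluorescence/OD600)."""
    if od600 <= 0:
        raise ValueError(f"OD600 must be > 0, got {od600}")
    return fluor / od600


def ethanol_yield(titer_g_per_l: float, initial_glucose_g_per_l: float = 20.0) -> float:
    """Product yield in g ethanol per g glucose, relative to the initial substrate.

    Default substrate is 2% glucose (20 g/L).
    """
    if titer_g_per_l < 0:
        raise ValueError("titer must be non-negative")
    if initial_glucose_g_per_l <= 0:
        raise ValueError("initial glucose must be > 0")
    return titer_g_per_l / initial_glucose_g_per_l


def linker_extension_length(
    aa_from: int, aa_to: int, geometry: GeometryParams = GeometryParams()
) -> float:
    """Contour-length gain (Å) from extending a flexible peptide linker.

    Uses the worm-like-chain contour approximation of 3.8 Å per residue:
    extending a 5-residue linker to 20 residues adds ~57 Å of reach.
    """
    if aa_from < 0 or aa_to < aa_from:
        raise ValueError(f"need 0 <= aa_from <= aa_to, got {aa_from}, {aa_to}")
    return (aa_to - aa_from) * geometry.aa_contour


def bp_span_length(n_bp: int, geometry: GeometryParams = GeometryParams()) -> float:
    """Physical span (Å) of n base pairs of B-DNA (3.3 Å/bp); 10 bp ≈ 33 Å."""
    if n_bp < 0:
        raise ValueError("n_bp must be non-negative")
    return n_bp * geometry.bp_rise


def reach_in_bp(length_angstrom: float, geometry: GeometryParams = GeometryParams()) -> int:
    """Whole base pairs spanned by a physical length (floor: partial bp are meaningless)."""
    if length_angstrom < 0:
        raise ValueError("length must be non-negative")
    # tiny epsilon so exact multiples of bp_rise are not lost to float rounding
    return math.floor(length_angstrom / geometry.bp_rise + 1e-9)


def summarize_replicates(values: Sequence[float], center: str = "mean"):
    """(center, sd) summary of replicate readings.

    ``center`` is "mean" (plate-reader convention) or "median" (cytometry
    convention); sd is the sample standard deviation (n−1), or 0.0 for a
    single replicate.
    """
    values = list(values)
    if not values:
        raise ValueError("no replicate values supplied")
    if center == "mean":
        c = statistics.fmean(values)
    elif center == "median":
        c = statistics.median(values)
    else:
        raise ValueError(f"center must be 'mean' or 'median', got {center!r}")
    sd = statistics.stdev(values) if len(values) > 1 else 0.0
    return c, sd
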