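"""SpCas9 NGG target-site scanning and TSS-window scoring for bacterial CRISPRa.

Bacterial CRISPRa only works when the activator is delivered to a narrow band
of positions upstream of the promoter's transcription start site: effective
sites sit roughly 80–90 bases upstream on the non-template strand and 50–80
bases upstream on the template strand. This module enumerates all NGG
protospacer-adjacent-motif (PAM) sites around a promoter, measures each
site's distance to the TSS under a configurable anchor convention, classifies
its strand relative to the gene, and scores it against a window model with
those bands as the default.

The PAM is strictly NGG (no NAG tolerance). Sites downstream of the TSS are
reported — they are the relevant ones for CRISPRi roadblock repression — but
always score 0 under the activation window model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import pandas as pd
import yaml

from .seqcore import (
    FORWARD,
    GenomicInterval,
    NucSequence,
    PromoterRecord,
    reverse_complement,
)

PROTOSPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = PROTOSPACER_LEN + PAM_LEN

NON_TEMPLATE = "non-template"
TEMPLATE = "template"

ANCHORS = ("pam_proximal_end", "pam_distal_end", "protospacer_center", "pam_start")
DEFAULT_ANCHOR = "pam_proximal_end"

#: Offset of each anchor base from the interval start, per site strand.
#: For a + site the protospacer occupies [s, s+20) and the PAM [s+20, s+23);
#: for a − site the (reverse-complemented) PAM occupies [s, s+3) and the
#: protospacer [s+3, s+23). "pam_proximal_end" is the protospacer base
#: adjacent to the PAM; "protospacer_center" is the 10th base from the 5′ end.
_ANCHOR_OFFSETS = {
    "+": {
        "pam_proximal_end": 19,
        "pam_distal_end": 0,
        "protospacer_center": 9,
        "pam_start": 20,
    },
    "-": {
        "pam_proximal_end": 3,
        "pam_distal_end": 22,
        "protospacer_center": 13,
        "pam_start": 2,
    },
}


@dataclass(frozen=True)
class TargetSite:
    """One protospacer+PAM occurrence on a promoter sequence.

    ``tss_distance`` is positive for sites upstream of the TSS (the CRISPRa
    regime), zero or negative for sites at/downstream of it (flagged, scored
    0 for activation). ``site_strand`` carries the protospacer+PAM;
    ``strand_class`` is relative to the gene: non-template iff the
    protospacer sequence appears on the coding (mRNA-identical) strand.
    """

    protospacer: str
    pam: str
    interval: GenomicInterval
    site_strand: str
    strand_class: Optional[str] = None
    tss_distance: Optional[int] = None
    window_score: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError(f"protospacer must be {PROTOSPACER_LEN} nt")
        if len(self.pam) != PAM_LEN or self.pam[1:] != "GG":
            raise ValueError(f"PAM must match NGG, got {self.pam!r}")

    @property
    def label(self) -> str:
        cls = {NON_TEMPLATE: "NT", TEMPLATE: "T", None: "?"}[self.strand_class]
        if self.tss_distance is None:
            return f"{cls}.{self.interval.start}"
        pos = -self.tss_distance if self.tss_distance >= 1 else 1 - self.tss_distance
        return f"{cls}{pos:+d}"


class WindowModelError(ValueError):
    """Raised for malformed window models (overlapping bands, bad scores)."""


@dataclass(frozen=True)
class WindowModel:
    """Distance-band scores per strand class, in bases upstream of the TSS.

    Bands are inclusive ``(lo, hi, score)`` triples of positive upstream
    distances; within a strand class they must not overlap and scores must
    lie in [0, 1]. The default reflects the empirically effective CRISPRa
    bands: non-template 80–90, template 50–80.
    """

    bands: dict

    def __post_init__(self) -> None:
        for cls, bands in self.bands.items():
            if cls not in (NON_TEMPLATE, TEMPLATE):
                raise WindowModelError(f"unknown strand class {cls!r}")
            ordered = sorted(bands)
            for lo, hi, score in ordered:
                if lo > hi:
                    raise WindowModelError(f"band ({lo}, {hi}) has lo > hi")
                if not 0.0 <= score <= 1.0:
                    raise WindowModelError(f"band score {score} outside [0, 1]")
            for (l1, h1, _), (l2, h2, _) in zip(ordered, ordered[1:]):
                if l2 <= h1:
                    raise WindowModelError(
                        f"overlapping bands ({l1}, {h1}) and ({l2}, {h2}) in {cls}"
                    )

    @classmethod
    def default(cls) -> "WindowModel":
        return cls(
            bands={
                NON_TEMPLATE: [(80, 90, 1.0)],
                TEMPLATE: [(50, 80, 1.0)],
            }
        )

    @classmethod
    def from_yaml(cls, path) -> "WindowModel":
        """Load bands from a YAML mapping: strand class -> list of [lo, hi, score]."""
        raw = yaml.safe_load(open(path))
        bands = {
            key: [(int(lo), int(hi), float(score)) for lo, hi, score in entries]
            for key, entries in raw.items()
        }
        return cls(bands=bands)

    def score(self, strand_class: str, tss_distance: int) -> float:
        if tss_distance < 1:  # at/downstream of TSS: no activation
            return 0.0
        for lo, hi, score in self.bands.get(strand_class, ()):
            if lo <= tss_distance <= hi:
                return score
        return 0.0


def anchor_index(site: TargetSite, anchor: str = DEFAULT_ANCHOR) -> int:
    """Genomic index (0-based) of the anchor base for a site."""
    if anchor not in ANCHORS:
        raise ValueError(f"unknown anchor {anchor!r}; choose from {ANCHORS}")
    return site.interval.start + _ANCHOR_OFFSETS[site.site_strand][anchor]


def distance_to_tss(
    site: TargetSite, promoter: PromoterRecord, anchor: str = DEFAULT_ANCHOR
) -> int:
    """Bases upstream of the +1 base for the site's anchor base.

    Positive means upstream (a base immediately 5′ of the TSS is at distance
    1); zero or negative means the anchor base sits at or downstream of the
    TSS, which is flagged by the caller and scores 0 for activation.
    """
    return promoter.upstream_distance(anchor_index(site, anchor))


def classify_strand(site: TargetSite, promoter: PromoterRecord) -> str:
    """Non-template iff the protospacer lies on the coding strand of the gene."""
    site_forward = site.site_strand == "+"
    gene_forward = promoter.gene_strand == FORWARD
    return NON_TEMPLATE if site_forward == gene_forward else TEMPLATE


def _scan_region(promoter: PromoterRecord, region: Optional[GenomicInterval]):
    length = len(promoter.seq)
    if region is None:
        return 0, length
    if not (0 <= region.start and region.end <= length):
        raise ValueError(
            f"region [{region.start}, {region.end}) outside sequence of length {length}"
        )
    return region.start, region.end


def find_pam_sites(
    promoter: PromoterRecord,
    region: Optional[GenomicInterval] = None,
    anchor: str = DEFAULT_ANCHOR,
) -> list[TargetSite]:
    """Enumerate every NGG site with a full 20-nt protospacer on either strand.

    Each site's interval covers protospacer+PAM (23 nt) and must lie inside
    ``region`` when one is given. Overlapping sites are all reported. The
    result is sorted by ``tss_distance`` ascending, ties broken + strand
    first. Window scores are left unset; see :func:`score_window` /
    :func:`rank_sites`.
    """
    bases = promoter.seq.bases
    lo, hi = _scan_region(promoter, region)
    if hi - lo < SITE_LEN:
        warnings.warn(
            f"scan region of length {hi - lo} is shorter than {SITE_LEN} nt; no sites possible"
        )
        return []

    sites: list[TargetSite] = []
    # + strand: protospacer at [s, s+20), PAM "NGG" at [s+20, s+23)
    for s in range(lo, hi - SITE_LEN + 1):
        if bases[s + 21] == "G" and bases[s + 22] == "G":
            sites.append(
                TargetSite(
                    protospacer=bases[s : s + 20],
                    pam=bases[s + 20 : s + 23],
                    interval=GenomicInterval(promoter.seq.id, s, s + SITE_LEN, "+"),
                    site_strand="+",
                )
            )
        # − strand: plus-strand "CCN" at [s, s+3), protospacer context at [s+3, s+23)
        if bases[s] == "C" and bases[s + 1] == "C":
            sites.append(
                TargetSite(
                    protospacer=reverse_complement(bases[s + 3 : s + 23]),
                    pam=reverse_complement(bases[s : s + 3]),
                    interval=GenomicInterval(promoter.seq.id, s, s + SITE_LEN, "-"),
                    site_strand="-",
                )
            )

    annotated = [
        replace(
            site,
            tss_distance=distance_to_tss(site, promoter, anchor),
            strand_class=classify_strand(site, promoter),
        )
        for site in sites
    ]
    annotated.sort(key=lambda s: (s.tss_distance, 0 if s.site_strand == "+" else 1))
    return annotated


def score_window(site: TargetSite, model: Optional[WindowModel] = None) -> float:
    """Score a site against the activation window model (0 outside all bands)."""
    if site.tss_distance is None or site.strand_class is None:
        raise ValueError("site must have tss_distance and strand_class computed")
    model = model or WindowModel.default()
    return model.score(site.strand_class, site.tss_distance)


REPORT_COLUMNS = [
    "label",
    "tss_position",
    "tss_distance",
    "strand_class",
    "site_strand",
    "start",
    "end",
    "protospacer",
    "pam",
    "window_score",
]


def rank_sites(
    promoter: PromoterRecord,
    model: Optional[WindowModel] = None,
    region: Optional[GenomicInterval] = None,
    anchor: str = DEFAULT_ANCHOR,
) -> tuple[list[TargetSite], pd.DataFrame]:
    """Find, measure, classify and score all sites; rank by usefulness.

    Returns the scored sites (sorted by descending window score, then
    ascending distance) and a tabular report. ``tss_position`` in the report
    uses the TSS=+1 / upstream-negative convention.
    """
    model = model or WindowModel.default()
    sites = [
        replace(site, window_score=score_window(site, model))
        for site in find_pam_sites(promoter, region=region, anchor=anchor)
    ]
    sites.sort(key=lambda s: (-s.window_score, s.tss_distance))
    rows = [
        {
            "label": s.label,
            "tss_position": -s.tss_distance if s.tss_distance >= 1 else 1 - s.tss_distance,
            "tss_distance": s.tss_distance,
            "strand_class": s.strand_class,
            "site_strand": s.site_strand,
            "start": s.interval.start,
            "end": s.interval.end,
            "protospacer": s.protospacer,
            "pam": s.pam,
            "window_score": s.window_score,
        }
        for s in sites
    ]
    return sites, pd.DataFrame(rows, columns=REPORT_COLUMNS)
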