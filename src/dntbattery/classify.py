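"""Specificity classification of DNT hits and most-sensitive-endpoint calls.

Two classification models coexist in the battery:

* NPC-family endpoints compare the BMC confidence interval of the DNT
  endpoint with those of its paired viability/cytotoxicity references:
  no CI overlap -> specific, overlap >= 10% -> unspecific, anything strictly
  in between -> borderline.  Multiple references are combined worst-case
  (the largest overlap wins).
* UKN-family endpoints use a ratio cutoff on the two point BMCs
  (viability BMC / endpoint BMC): >= 1.3 for NCC migration (UKN2), >= 4 for
  LUHMES neurite area (UKN4), >= 3 for peripheral-neuron neurite area (UKN5)
  calls the hit specific; otherwise unspecific.  No borderline category
  exists for these assays.

A censored DNT BMC is never a hit.  When every confidence interval is
degenerate (noise-free data make the bootstrap collapse to a point), interval
overlap is undefined; classification then falls back to the viability/DNT
BMC ratio — at or below 1 unspecific, at or above 3 specific (the battery's
3-fold similarity range), between the two borderline — and records that
basis on the call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .fitting import BMCEstimate

CLASSIFICATIONS = ("specific", "borderline", "unspecific", "no_hit")
UKN_RATIO_CUTOFFS = {"ukn2": 1.3, "ukn4": 4.0, "ukn5": 3.0}

#: degenerate-CI fallback: viability/DNT BMC ratio bounds
FALLBACK_RATIO_SPECIFIC = 3.0
FALLBACK_RATIO_UNSPECIFIC = 1.0


@dataclass
class HitCall:
    compound_id: str
    endpoint_id: str
    classification: str
    basis: str  # "ci_overlap" | "viability_ratio" | "censored"
    overlap_fraction: float | None = None
    ratio_value: float | None = None
    reference_endpoint_used: str = ""

    def __post_init__(self) -> None:
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")


def _width(ci: tuple[float, float]) -> float:
    return ci[1] - ci[0]


def _degenerate(ci: tuple[float, float], rel: float = 1e-9) -> bool:
    lo, hi = ci
    return (hi - lo) <= rel * max(abs(hi), abs(lo), 1e-300)


def ci_overlap_fraction(
    ci_dnt: tuple[float, float],
    ci_ref: tuple[float, float],
    denominator: str = "dnt",
) -> float:
    """Fractional overlap of two BMC confidence intervals.

    Length of the intersection divided by the length of the DNT-endpoint
    interval (configurable to the reference interval or the shorter of the
    two); 0 when disjoint.  A zero-length DNT interval is measured against
    the reference interval instead; two zero-length intervals overlap fully
    when equal and not at all otherwise.
    """
    (a, b), (c, d) = ci_dnt, ci_ref
    if not (a <= b and c <= d):
        raise ValueError("confidence intervals must satisfy lower <= upper")
    inter = max(0.0, min(b, d) - max(a, c))
    if denominator == "dnt":
        den = _width(ci_dnt) if _width(ci_dnt) > 0 else _width(ci_ref)
    elif denominator == "ref":
        den = _width(ci_ref) if _width(ci_ref) > 0 else _width(ci_dnt)
    elif denominator == "min":
        widths = [w for w in (_width(ci_dnt), _width(ci_ref)) if w > 0]
        den = min(widths) if widths else 0.0
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    if den <= 0:  # both intervals are points
        return 1.0 if a == c else 0.0
    return min(1.0, inter / den)


def _ratio_call(ratio: float) -> str:
    if ratio <= FALLBACK_RATIO_UNSPECIFIC:
        return "unspecific"
    if ratio >= FALLBACK_RATIO_SPECIFIC:
        return "specific"
    return "borderline"


def classify_npc(
    bmc_dnt: BMCEstimate,
    bmc_refs: list[BMCEstimate],
    overlap_unspecific: float = 0.10,
    denominator: str = "dnt",
) -> HitCall:
    """CI-overlap classification for NPC-family endpoints (worst case wins)."""
    if not bmc_refs:
        raise ConfigurationError(
            f"no reference endpoints configured for {bmc_dnt.endpoint_id or 'endpoint'}"
        )
    comp, ep = bmc_dnt.compound_id, bmc_dnt.endpoint_id
    if bmc_dnt.censored:
        return HitCall(comp, ep, "no_hit", "censored")
    active = [r for r in bmc_refs if not r.censored]
    if not active:
        return HitCall(comp, ep, "specific", "ci_overlap", overlap_fraction=0.0)
    all_degenerate = (
        bmc_dnt.has_ci
        and _degenerate(bmc_dnt.ci)
        and all(r.has_ci and _degenerate(r.ci) for r in active)
    )
    if all_degenerate:
        # interval overlap carries no information; use the BMC ratio instead
        worst = min(active, key=lambda r: r.bmc / bmc_dnt.bmc)
        ratio = worst.bmc / bmc_dnt.bmc
        return HitCall(
            comp, ep, _ratio_call(ratio), "viability_ratio",
            ratio_value=float(ratio), reference_endpoint_used=worst.endpoint_id,
        )
    fractions = [
        (ci_overlap_fraction(bmc_dnt.ci, r.ci, denominator=denominator), r) for r in active
    ]
    frac, worst = max(fractions, key=lambda t: t[0])
    if frac == 0.0:
        cls = "specific"
    elif frac >= overlap_unspecific:
        cls = "unspecific"
    else:
        cls = "borderline"
    return HitCall(
        comp, ep, cls, "ci_overlap",
        overlap_fraction=float(frac), reference_endpoint_used=worst.endpoint_id,
    )


def classify_ukn(
    assay: str,
    bmc_endpoint: BMCEstimate,
    bmc_viability: BMCEstimate,
    cutoffs: dict[str, float] | None = None,
) -> HitCall:
    """Ratio-cutoff classification for the UKN assays (cutoff inclusive)."""
    cutoffs = cutoffs or UKN_RATIO_CUTOFFS
    assay = assay.lower()
    if assay not in cutoffs:
        raise ConfigurationError(f"unknown UKN assay {assay!r}")
    comp, ep = bmc_endpoint.compound_id, bmc_endpoint.endpoint_id
    if bmc_endpoint.censored:
        return HitCall(comp, ep, "no_hit", "censored")
    if bmc_viability.censored:
        # no viability loss within the tested range: ratio effectively infinite
        return HitCall(
            comp, ep, "specific", "viability_ratio",
            ratio_value=float(np.inf), reference_endpoint_used=bmc_viability.endpoint_id,
        )
    ratio = bmc_viability.bmc / bmc_endpoint.bmc
    cls = "specific" if ratio >= cutoffs[assay] else "unspecific"
    return HitCall(
        comp, ep, cls, "viability_ratio",
        ratio_value=float(ratio), reference_endpoint_used=bmc_viability.endpoint_id,
    )


@dataclass
class CompoundProfile:
    """All endpoint evidence for one compound, plus its MSE."""

    compound_id: str
    bmcs: dict[str, BMCEstimate] = field(default_factory=dict)
    hit_calls: dict[str, HitCall] = field(default_factory=dict)

    @property
    def mse(self) -> tuple[str, float] | None:
        return most_sensitive_endpoint(self)

    @property
    def mse_endpoint(self) -> str | None:
        m = self.mse
        return m[0] if m else None

    @property
    def mse_bmc(self) -> float | None:
        m = self.mse
        return m[1] if m else None


def most_sensitive_endpoint(profile: CompoundProfile) -> tuple[str, float] | None:
    """Lowest BMC among endpoints classified specific (ties: lexicographic).

    Unspecific/borderline BMCs never win; returns ``None`` when the compound
    has no specific hit.
    """
    specific = [
        (profile.bmcs[ep].bmc, ep)
        for ep, call in profile.hit_calls.items()
        if call.classification == "specific"
        and ep in profile.bmcs
        and not profile.bmcs[ep].censored
    ]
    if not specific:
        return None
    bmc, ep = min(specific, key=lambda t: (t[0], t[1]))
    return ep, float(bmc)
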