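"""Ground-truth-labelled synthetic screens emulating the DNT battery layout.

The generator mirrors how the battery plates compounds: a geometric serial
dilution (typically 1:3 with 7 concentrations) plus solvent controls, with
3-5 replicate wells per condition.  Each scenario pairs one DNT endpoint
curve with one or more viability/cytotoxicity reference curves whose shift
relative to the DNT curve encodes the intended specificity label
(specific / borderline / unspecific / negative), so every downstream stage
can be validated against known truth.

Noise is additive Gaussian on the percent-of-control scale; control wells are
drawn around 100 with the same spread so that re-normalization downstream is
non-degenerate.  Seeds are mandatory — there is no hidden global random
state, and a fixed seed reproduces the output tables byte for byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import curves
from .errors import ConfigurationError

CURVE_MODELS = ("sigmoid_decreasing", "sigmoid_increasing", "bell", "flat")
LABELS = ("specific", "borderline", "unspecific", "negative")

#: viability/DNT BMC ratio bounds delimiting the intended-label constructions
#: (mirrors the noiseless classification fallback in ``classify``).
RATIO_SPECIFIC = 3.0
RATIO_UNSPECIFIC = 1.0


@dataclass(frozen=True)
class TrueCurveSpec:
    """Noiseless concentration-response truth for one endpoint.

    ``bottom``/``top`` are percent of control; ``ec50`` (and, for bells, the
    descending-limb ``ec50_secondary``) are in µM; ``hill`` is dimensionless
    and positive (orientation is carried by ``model``); ``noise_sd`` is the
    well-to-well Gaussian SD in percent of control.  ``model='flat'`` is a
    constant 100% response (an inactive endpoint).
    """

    model: str
    bottom: float = 100.0
    top: float = 100.0
    ec50: float = 1.0
    hill: float = 1.0
    ec50_secondary: float | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in CURVE_MODELS:
            raise ValueError(f"unknown curve model {self.model!r}")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bottom > self.top:
            raise ValueError("bottom must not exceed top")
        if self.model == "bell":
            if self.ec50_secondary is None:
                raise ValueError("bell curves require ec50_secondary")
            if self.ec50_secondary <= self.ec50:
                raise ValueError("ec50_secondary must exceed ec50 for bells")

    def response(self, conc) -> np.ndarray:
        """Noiseless mean response (percent of control) at ``conc`` µM."""
        c = np.asarray(conc, dtype=float)
        if self.model == "flat":
            return np.full_like(c, curves.CONTROL_LEVEL, dtype=float)
        if self.model == "sigmoid_decreasing":
            return curves.sigmoid(c, self.bottom, self.top, np.log10(self.ec50), -self.hill)
        if self.model == "sigmoid_increasing":
            return curves.sigmoid(c, self.bottom, self.top, np.log10(self.ec50), self.hill)
        return curves.bell(
            c,
            self.bottom,
            self.top,
            np.log10(self.ec50),
            self.hill,
            np.log10(self.ec50_secondary),
            self.hill,
        )

    @property
    def direction(self) -> str:
        """Adverse direction implied by the curve shape."""
        if self.model == "sigmoid_increasing":
            return "increase"
        if self.model == "bell":
            return "both"
        return "decrease"

    def true_bmc(self, bmr: float, direction: str | None = None, c_max: float = np.inf) -> float | None:
        """Analytic BMC of the noiseless curve, ``None`` when never reached.

        Sigmoids are solved in closed form; bells by bracketing on each limb.
        For bells the lowest crossing in the adverse direction wins, i.e. the
        ascending-limb crossing unless only a decrease is deemed adverse.
        """
        if direction is None:
            direction = self.direction
        if self.model == "flat":
            return None
        if self.model == "sigmoid_decreasing":
            return curves.sigmoid_bmc(
                self.bottom, self.top, np.log10(self.ec50), -self.hill, bmr, direction, c_max
            )
        if self.model == "sigmoid_increasing":
            return curves.sigmoid_bmc(
                self.bottom, self.top, np.log10(self.ec50), self.hill, bmr, direction, c_max
            )
        c_hi = c_max if np.isfinite(c_max) else self.ec50_secondary * 1e4
        return curves.bmc_numeric(self.response, bmr, direction, c_hi)


def make_dilution_series(top_conc: float, factor: float, n: int) -> np.ndarray:
    """Geometric serial dilution, highest concentration first (µM).

    Element ``i`` equals ``top_conc / factor**i``; the solvent control
    (concentration 0) is not part of the series — it is emitted as its own
    well records by the simulators.
    """
    if top_conc <= 0:
        raise ValueError("top_conc must be positive")
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    if n < 1:
        raise ValueError("need at least one concentration")
    return top_conc / factor ** np.arange(n, dtype=float)


@dataclass(frozen=True)
class DilutionSpec:
    top_conc: float = 20.0
    factor: float = 3.0
    n_concentrations: int = 7

    def concentrations(self) -> np.ndarray:
        return make_dilution_series(self.top_conc, self.factor, self.n_concentrations)


@dataclass(frozen=True)
class ScenarioSpec:
    """One compound x DNT-endpoint construction with paired references.

    ``viability_curves`` maps each reference endpoint label to
    ``(role, TrueCurveSpec)`` where role is ``viability`` (e.g. CTB) or
    ``cytotoxicity`` (e.g. LDH).  ``assay_family`` selects the downstream
    classification rule: ``npc`` uses CI overlap, ``ukn2/ukn4/ukn5`` use the
    viability/endpoint BMC ratio.  ``bmr_dnt``/``bmr_viability`` are the
    benchmark responses (percent deviation from control) read off each curve.
    """

    compound_id: str
    dnt_endpoint: str
    dnt_curve: TrueCurveSpec
    viability_curves: dict[str, tuple[str, TrueCurveSpec]]
    intended_label: str
    assay_family: str = "npc"
    dilution: DilutionSpec = field(default_factory=DilutionSpec)
    n_replicates: int = 5
    bmr_dnt: float = 20.0
    bmr_viability: float = 20.0

    def __post_init__(self) -> None:
        if self.intended_label not in LABELS:
            raise ValueError(f"unknown intended label {self.intended_label!r}")
        if self.assay_family not in ("npc", "ukn2", "ukn4", "ukn5"):
            raise ValueError(f"unknown assay family {self.assay_family!r}")
        if self.n_replicates < 3:
            raise ValueError("need at least 3 replicate wells")
        if self.dilution.n_concentrations < 5:
            raise ValueError("need at least 5 concentrations")
        if self.assay_family != "npc" and self.intended_label == "borderline":
            raise ValueError("UKN assays define no borderline category")
        self._assert_label_consistency()

    # -- ground-truth bookkeeping -------------------------------------------------

    def _ratio_cutoff(self) -> tuple[float, float]:
        """(specific-at-or-above, unspecific-at-or-below) viability/DNT ratio."""
        if self.assay_family == "npc":
            return RATIO_SPECIFIC, RATIO_UNSPECIFIC
        cut = {"ukn2": 1.3, "ukn4": 4.0, "ukn5": 3.0}[self.assay_family]
        return cut, cut

    def true_dnt_bmc(self) -> float | None:
        c_max = self.dilution.top_conc
        return self.dnt_curve.true_bmc(self.bmr_dnt, c_max=c_max)

    def true_viability_ratio(self) -> float:
        """min over references of (viability BMC / DNT BMC); inf when clean."""
        dnt = self.true_dnt_bmc()
        if dnt is None:
            return np.inf
        c_max = self.dilution.top_conc
        ratios = []
        for _, (_, spec) in sorted(self.viability_curves.items()):
            ref = spec.true_bmc(self.bmr_viability, c_max=c_max)
            ratios.append(np.inf if ref is None else ref / dnt)
        return min(ratios) if ratios else np.inf

    def _assert_label_consistency(self) -> None:
        dnt = self.true_dnt_bmc()
        if self.intended_label == "negative":
            if dnt is not None:
                raise ValueError(
                    f"{self.compound_id}: negative scenario but DNT BMC {dnt:.3g} µM is reached"
                )
            return
        if dnt is None:
            raise ValueError(f"{self.compound_id}: {self.intended_label} scenario but DNT BMC censored")
        r = self.true_viability_ratio()
        hi, lo = self._ratio_cutoff()
        ok = {
            "specific": r >= hi,
            "unspecific": r <= lo if self.assay_family == "npc" else r < lo,
            "borderline": lo < r < hi,
        }[self.intended_label]
        if not ok:
            raise ValueError(
                f"{self.compound_id}: viability/DNT BMC ratio {r:.3g} inconsistent "
                f"with intended label {self.intended_label!r}"
            )


def _series_rng(seed: int, compound: str, endpoint: str) -> np.random.Generator:
    """Deterministic per-series stream derived from the master seed."""
    tag = zlib.crc32(f"{compound}|{endpoint}".encode())
    return np.random.default_rng([seed, tag])


def simulate_endpoint(
    spec: TrueCurveSpec,
    concentrations: np.ndarray,
    n_replicates: int,
    seed: int | np.random.Generator,
    include_control: bool = True,
) -> pd.DataFrame:
    """Replicate-level percent-of-control wells for one endpoint.

    Each treated well is ``curve(c) + N(0, noise_sd)``; control wells
    (concentration 0) are drawn around 100 with the same spread.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    rows = []
    levels = list(conc) + ([0.0] if include_control else [])
    for c in levels:
        mu = curves.CONTROL_LEVEL if c == 0.0 else float(spec.response(c))
        for rep in range(1, n_replicates + 1):
            val = mu + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
            rows.append({"concentration_uM": c, "replicate": rep, "value_pct_control": val})
    return pd.DataFrame(rows)


def simulate_battery(
    scenarios: list[ScenarioSpec], seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full screen; returns (well table, ground-truth table).

    The well table has one row per compound x endpoint x concentration x
    replicate with columns compound, endpoint, concentration_uM, replicate,
    value_pct_control, role, plate_id.  The truth table records each
    scenario's intended label, the analytic DNT BMC of the noiseless curve at
    the scenario's BMR, and the worst-case viability/DNT BMC ratio.
    """
    seen: set[tuple[str, str]] = set()
    well_frames = []
    truth_rows = []
    for sc in scenarios:
        key = (sc.compound_id, sc.dnt_endpoint)
        if key in seen:
            raise ConfigurationError(f"duplicate scenario for compound/endpoint {key}")
        seen.add(key)
        conc = sc.dilution.concentrations()
        plate = f"{sc.compound_id}:{sc.dnt_endpoint}"
        endpoints = [(sc.dnt_endpoint, "dnt", sc.dnt_curve)]
        endpoints += [
            (label, role, spec) for label, (role, spec) in sorted(sc.viability_curves.items())
        ]
        for label, role, spec in endpoints:
            df = simulate_endpoint(spec, conc, sc.n_replicates, _series_rng(seed, sc.compound_id, label))
            df.insert(0, "compound", sc.compound_id)
            df.insert(1, "endpoint", label)
            df["role"] = role
            df["plate_id"] = plate
            well_frames.append(df)
        dnt_bmc = sc.true_dnt_bmc()
        truth_rows.append(
            {
                "compound": sc.compound_id,
                "dnt_endpoint": sc.dnt_endpoint,
                "assay_family": sc.assay_family,
                "intended_label": sc.intended_label,
                "bmr_dnt": sc.bmr_dnt,
                "bmr_viability": sc.bmr_viability,
                "true_bmc_uM": np.nan if dnt_bmc is None else dnt_bmc,
                "true_viability_ratio": sc.true_viability_ratio(),
            }
        )
    wells = pd.concat(well_frames, ignore_index=True)
    return wells, pd.DataFrame(truth_rows)


def default_battery(noise_sd: float = 5.0) -> list[ScenarioSpec]:
    """The package's canonical 12-scenario screen.

    Four specific, one borderline, three unspecific and four negative
    constructions across NPC-style (CI overlap) and UKN-style (BMC ratio)
    endpoint families, on a 7-point 1:3 dilution from 20 µM with 5
    replicates — the plate design of the neurosphere assays.
    """

    def dec(ec50, hill=2.0, bottom=0.0, top=100.0):
        return TrueCurveSpec("sigmoid_decreasing", bottom, top, ec50, hill, noise_sd=noise_sd)

    def flat():
        return TrueCurveSpec("flat", noise_sd=noise_sd)

    npc_refs = lambda ctb, ldh: {"CTB": ("viability", ctb), "LDH": ("cytotoxicity", ldh)}

    return [
        # -- specific hits ---------------------------------------------------
        ScenarioSpec("C01", "NPC5", dec(0.5), npc_refs(flat(), flat()), "specific"),
        ScenarioSpec("C02", "NPC1", dec(0.4), npc_refs(dec(15.0, hill=3.0), flat()), "specific"),
        ScenarioSpec(
            "C03", "UKN2", dec(2.0), {"UKN2_viab": ("viability", dec(12.0))},
            "specific", assay_family="ukn2", bmr_dnt=25.0, bmr_viability=10.0,
        ),
        ScenarioSpec(
            "C04", "UKN4", dec(1.0), {"UKN4_viab": ("viability", flat())},
            "specific", assay_family="ukn4", bmr_dnt=25.0, bmr_viability=25.0,
        ),
        # -- borderline (NPC migration endpoint, LDH-only reference) ---------
        ScenarioSpec("C05", "NPC2a", dec(0.8), {"LDH": ("cytotoxicity", dec(1.4))}, "borderline"),
        # -- unspecific hits -------------------------------------------------
        ScenarioSpec("C06", "NPC1", dec(1.0), npc_refs(dec(1.0), flat()), "unspecific"),
        ScenarioSpec("C07", "NPC5", dec(2.0), npc_refs(dec(2.2), dec(1.7)), "unspecific"),
        ScenarioSpec(
            "C08", "UKN4", dec(3.0), {"UKN4_viab": ("viability", dec(6.0))},
            "unspecific", assay_family="ukn4", bmr_dnt=25.0, bmr_viability=25.0,
        ),
        # -- negatives -------------------------------------------------------
        ScenarioSpec("C09", "NPC1", flat(), npc_refs(flat(), flat()), "negative"),
        ScenarioSpec("C10", "NPC5", flat(), npc_refs(flat(), dec(5.0)), "negative"),
        ScenarioSpec(
            "C11", "UKN2", flat(), {"UKN2_viab": ("viability", dec(8.0))},
            "negative", assay_family="ukn2", bmr_dnt=25.0, bmr_viability=10.0,
        ),
        ScenarioSpec("C12", "NPC2a", flat(), {"LDH": ("cytotoxicity", flat())}, "negative"),
    ]
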