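"""Screen-table ingestion, percent-of-control normalization, significance flags.

A screen table is delimited text with one row per well:
``compound, endpoint, concentration_uM, replicate, value, role, plate_id``
(``value_pct_control`` is accepted as an alias for ``value``; ``role`` and
``plate_id`` are optional).  Solvent controls are rows with concentration 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ConfigurationError, NormalizationError, SchemaError

REQUIRED_COLUMNS = ("compound", "endpoint", "concentration_uM", "replicate", "value")
VALUE_ALIASES = ("value", "value_pct_control", "raw_value")


@dataclass
class ResponseSeries:
    """Replicate-level percent-of-control responses for one compound x endpoint.

    ``concentrations`` are the strictly increasing non-control levels (µM);
    ``values[i]`` holds the replicate wells at ``concentrations[i]``.
    """

    compound_id: str
    endpoint_id: str
    concentrations: np.ndarray
    values: list[np.ndarray]
    direction: str = "decrease"
    role: str = "dnt"
    reference_endpoints: list[str] = field(default_factory=list)
    #: normalized solvent-control wells (mean 100); lets the bootstrap
    #: propagate control-mean uncertainty by renormalizing each resample
    control_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValueError("series concentrations must be positive (controls live elsewhere)")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if len(self.values) != len(self.concentrations):
            raise ValueError("values and concentrations length mismatch")
        self.values = [np.asarray(v, dtype=float) for v in self.values]

    @property
    def means(self) -> np.ndarray:
        return np.array([v.mean() for v in self.values])

    @property
    def ns(self) -> np.ndarray:
        return np.array([len(v) for v in self.values])

    @property
    def sems(self) -> np.ndarray:
        # sample SD / sqrt(n); NaN where n < 2
        return np.array(
            [v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan for v in self.values]
        )

    @property
    def c_max(self) -> float:
        return float(self.concentrations[-1])

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """(concentration, response) pairs for every well, for fitting."""
        c = np.repeat(self.concentrations, self.ns)
        y = np.concatenate(self.values)
        return c, y


def read_screen_table(path, pairing: dict[str, list[str]], sep: str = "\t") -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Read a well table and validate it against an endpoint-pairing map.

    ``pairing`` maps each DNT endpoint to its viability/cytotoxicity
    reference endpoints (e.g. migration endpoints may be paired LDH-only).
    Raises :class:`SchemaError` on missing columns and
    :class:`ConfigurationError` for DNT endpoints without a pairing.
    """
    df = pd.read_csv(path, sep=sep)
    df = _validate_wells(df)
    dnt_endpoints = set(df.loc[df["role"] == "dnt", "endpoint"])
    unpaired = sorted(dnt_endpoints - set(pairing))
    if unpaired:
        raise ConfigurationError(f"DNT endpoints without reference pairing: {unpaired}")
    known = dnt_endpoints | {r for refs in pairing.values() for r in refs}
    unknown = sorted(set(df["endpoint"]) - known - set(pairing))
    if unknown:
        raise ConfigurationError(f"endpoints absent from the pairing configuration: {unknown}")
    return df, {k: list(v) for k, v in pairing.items()}


def _validate_wells(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for alias in VALUE_ALIASES[1:]:
        if "value" not in df.columns and alias in df.columns:
            df = df.rename(columns={alias: "value"})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"screen table is missing required column(s): {missing}")
    if "role" not in df.columns:
        df["role"] = "dnt"
    if "plate_id" not in df.columns:
        df["plate_id"] = ""
    if (df["concentration_uM"] < 0).any():
        raise SchemaError("negative concentrations in screen table")
    return df


def percent_of_control(wells: pd.DataFrame, min_controls: int = 2) -> pd.DataFrame:
    """Normalize each well to the mean of its matched solvent controls x 100.

    Controls are matched per compound x endpoint x plate; when a plate has no
    controls for that pair the endpoint-wide controls are pooled instead.
    The control mean maps to exactly 100, so the operation is idempotent on
    data already expressed as percent of control.
    """
    wells = _validate_wells(wells)
    out = wells.copy()
    out["value_pct_control"] = np.nan
    ctrl = wells[wells["concentration_uM"] == 0]
    if ctrl.empty:
        raise NormalizationError("no solvent-control wells (concentration 0) found")
    for (comp, ep), grp in wells.groupby(["compound", "endpoint"], sort=False):
        for plate, sub in grp.groupby("plate_id", sort=False):
            cc = sub.loc[sub["concentration_uM"] == 0, "value"]
            if len(cc) < min_controls:  # fall back to endpoint-wide pooling
                cc = grp.loc[grp["concentration_uM"] == 0, "value"]
            if len(cc) < min_controls:
                raise NormalizationError(
                    f"fewer than {min_controls} control wells for {comp}/{ep}"
                )
            mean = cc.mean()
            if mean <= 0:
                raise NormalizationError(f"non-positive control mean for {comp}/{ep}")
            out.loc[sub.index, "value_pct_control"] = sub["value"] / mean * 100.0
    return out


def flag_significant(wells: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-concentration significance flags for each compound x endpoint.

    One-way ANOVA across all concentration groups (controls included) gates
    Bonferroni-corrected two-sided t-tests of each concentration against the
    solvent control; the correction spans only the concentration-vs-control
    comparisons.  ``adjusted p <= alpha`` flags the concentration (the
    boundary is inclusive).
    """
    wells = _validate_wells(wells)
    value_col = "value_pct_control" if "value_pct_control" in wells.columns else "value"
    rows = []
    for (comp, ep), grp in wells.groupby(["compound", "endpoint"], sort=False):
        ctrl = grp.loc[grp["concentration_uM"] == 0, value_col].to_numpy()
        treated = {
            c: g[value_col].to_numpy()
            for c, g in grp[grp["concentration_uM"] > 0].groupby("concentration_uM")
        }
        if len(ctrl) < 2 or not treated or any(len(v) < 2 for v in treated.values()):
            raise AnalysisError(f"insufficient replication for {comp}/{ep}")
        groups = [ctrl] + list(treated.values())
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            anova_p = 1.0  # identical constant everywhere: nothing to test
        else:
            anova_p = float(stats.f_oneway(*groups).pvalue)
            if np.isnan(anova_p):
                anova_p = 1.0
        k = len(treated)
        for c, vals in sorted(treated.items()):
            if np.ptp(vals) == 0 and np.ptp(ctrl) == 0:
                p_adj = 1.0 if vals[0] == ctrl[0] else 0.0
            else:
                p = float(stats.ttest_ind(vals, ctrl, equal_var=True).pvalue)
                p_adj = min(1.0, p * k) if np.isfinite(p) else 1.0
            rows.append(
                {
                    "compound": comp,
                    "endpoint": ep,
                    "concentration_uM": c,
                    "anova_p": anova_p,
                    "p_adjusted": p_adj,
                    "significant": bool(anova_p <= alpha and p_adj <= alpha),
                }
            )
    return pd.DataFrame(rows)


def build_series(
    normalized: pd.DataFrame,
    directions: dict[str, str] | None = None,
    pairing: dict[str, list[str]] | None = None,
) -> dict[tuple[str, str], ResponseSeries]:
    """Assemble :class:`ResponseSeries` from a normalized well table."""
    directions = directions or {}
    pairing = pairing or {}
    out: dict[tuple[str, str], ResponseSeries] = {}
    for (comp, ep), grp in normalized.groupby(["compound", "endpoint"], sort=False):
        treated = grp[grp["concentration_uM"] > 0]
        conc = np.sort(treated["concentration_uM"].unique())
        values = [
            treated.loc[treated["concentration_uM"] == c, "value_pct_control"].to_numpy()
            for c in conc
        ]
        role = grp["role"].iloc[0] if "role" in grp.columns else "dnt"
        controls = grp.loc[grp["concentration_uM"] == 0, "value_pct_control"].to_numpy()
        out[(comp, ep)] = ResponseSeries(
            compound_id=comp,
            endpoint_id=ep,
            concentrations=conc,
            values=values,
            direction=directions.get(ep, "decrease"),
            role=role,
            reference_endpoints=list(pairing.get(ep, [])),
            control_values=controls if len(controls) else None,
        )
    return out
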