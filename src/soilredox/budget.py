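"""Per-bottle electron ledgers and treatment-group statistics.

Turns measured incubation endpoints (Fe(II), sulfate, methane, chlorophenol
species) into electron-equivalent budgets for the four anaerobic reduction
processes — Fe(III) reduction, sulfate reduction, reductive dechlorination
of PCP, and methanogenesis — after subtracting a sterile abiotic baseline,
then summarises groups with one-way ANOVA, Tukey HSD and a compact letter
display.

Conventions:

* Fe(III) reduction electrons come from the *rise* of HCl-extractable
  Fe(II) over the sterile baseline (1 e- per mol Fe).
* Sulfate reduction electrons come from the *drop* of sulfate below the
  sterile baseline (8 e- per mol SO4).
* Dechlorination electrons are computed from accumulated products
  (TeCP/TCP/DCP), not from PCP disappearance, so abiotic sorption losses
  do not inflate the ledger.
* Methanogenesis electrons come from headspace CH4 (8 eeq per mol; the
  sterile baseline is zero since sterile soil releases no methane).
* Negative baseline-corrected deltas are clipped to zero with a logged
  warning: measurement noise makes small negatives routine.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stoichiometry import (
    MOLAR_MASS,
    BottleGeometry,
    ChlorophenolSpecies,
    Measurement,
    Unit,
    dechlorination_eeq,
    eeq_per_mol,
    mass_to_micromoles,
    permil_to_micromoles,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GROUPS",
    "AMENDMENTS",
    "TreatmentLabel",
    "IncubationEndpoint",
    "ElectronLedger",
    "BaselineError",
    "abiotic_baseline",
    "compute_baselines",
    "compute_ledger",
    "ledgers_to_frame",
    "compute_ledgers",
    "summarize_groups",
    "compact_letter_display",
]

GROUPS = ("sterile_abiotic", "biotic", "biotic_molybdate")
AMENDMENTS = ("control", "AQDS", "biochar")

#: chlorophenol product species paired with their endpoint field names
_PRODUCTS = (
    ("tecp", ChlorophenolSpecies.TeCP_2345),
    ("tcp", ChlorophenolSpecies.TCP_345),
    ("dcp", ChlorophenolSpecies.DCP_35),
)


class BaselineError(ValueError):
    """No sterile abiotic bottles available to define a baseline."""


@dataclass(frozen=True)
class TreatmentLabel:
    """(group, amendment, replicate) identity of one bottle."""

    group: str
    amendment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.amendment not in AMENDMENTS:
            raise ValueError(
                f"unknown amendment {self.amendment!r}; expected one of {AMENDMENTS}"
            )


@dataclass
class IncubationEndpoint:
    """Measured chemistry of one bottle at the end of the incubation.

    Concentrations are per gram of air-dry soil (mg/g or ug/g), gases in
    permil of headspace, DOC/DON in mg per kg soil, Eh in mV.
    """

    label: TreatmentLabel
    fe2: float  # mg/g
    sulfate: float  # mg/g
    ch4: float  # permil headspace
    pcp: float  # ug/g
    tecp: float = 0.0  # ug/g
    tcp: float = 0.0  # ug/g
    dcp: float = 0.0  # ug/g
    nitrate: float | None = None  # mg/g
    co2: float | None = None  # permil headspace
    ph: float | None = None
    eh: float | None = None  # mV
    doc: float | None = None  # mg/kg
    don: float | None = None  # mg/kg

    def __post_init__(self) -> None:
        for name in ("fe2", "sulfate", "ch4", "pcp", "tecp", "tcp", "dcp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} concentration cannot be negative")


@dataclass(frozen=True)
class ElectronLedger:
    """Electron equivalents (umol e- per bottle) consumed by each process."""

    label: TreatmentLabel
    e_fe: float
    e_so4: float
    e_dechlor: float
    e_ch4: float

    @property
    def e_total(self) -> float:
        return self.e_fe + self.e_so4 + self.e_dechlor + self.e_ch4


def abiotic_baseline(
    endpoints: list[IncubationEndpoint],
    analyte: str,
    matching: str = "matched",
    amendment: str | None = None,
) -> float:
    """Baseline value of ``analyte`` from the sterile abiotic bottles.

    ``matching='matched'`` averages sterile bottles with the given
    ``amendment`` (falling back to the pooled sterile mean, with a logged
    notice, when no matching bottle exists); ``matching='pooled'`` averages
    all sterile bottles.
    """
    sterile = [e for e in endpoints if e.label.group == "sterile_abiotic"]
    if not sterile:
        raise BaselineError("no sterile_abiotic bottles: cannot define a baseline")
    if matching not in ("matched", "pooled"):
        raise ValueError(f"unknown baseline matching strategy {matching!r}")
    if matching == "matched":
        if amendment is None:
            raise ValueError("matched baseline requires an amendment")
        subset = [e for e in sterile if e.label.amendment == amendment]
        if subset:
            return float(np.mean([getattr(e, analyte) for e in subset]))
        logger.warning(
            "no sterile bottle with amendment %r for analyte %s; "
            "falling back to pooled sterile mean",
            amendment,
            analyte,
        )
    return float(np.mean([getattr(e, analyte) for e in sterile]))


def compute_baselines(
    endpoints: list[IncubationEndpoint],
    amendment: str,
    matching: str = "matched",
) -> dict[str, float]:
    """Per-analyte baselines (fe2, sulfate) for bottles of one amendment."""
    return {
        analyte: abiotic_baseline(endpoints, analyte, matching, amendment)
        for analyte in ("fe2", "sulfate")
    }


def _clip(delta: float, what: str, label: TreatmentLabel) -> float:
    if delta < 0:
        logger.warning(
            "negative baseline-corrected %s delta (%.4g) for %s/%s rep %d; "
            "clipping to 0",
            what,
            delta,
            label.group,
            label.amendment,
            label.replicate,
        )
        return 0.0
    return delta


def compute_ledger(
    endpoint: IncubationEndpoint,
    baselines: dict[str, float],
    geometry: BottleGeometry | None = None,
) -> ElectronLedger:
    """Electron ledger of one bottle given its analyte baselines.

    ``baselines`` must hold the (amendment-resolved) sterile means for
    ``fe2`` and ``sulfate`` in mg/g.
    """
    geometry = geometry or BottleGeometry()
    for required in ("fe2", "sulfate"):
        if required not in baselines:
            raise ValueError(f"baseline for {required!r} missing")
    lab = endpoint.label

    d_fe = _clip(endpoint.fe2 - baselines["fe2"], "Fe(II)", lab)
    e_fe = mass_to_micromoles(
        Measurement("fe2", d_fe, Unit.mg_per_g), geometry, MOLAR_MASS["Fe"]
    ) * eeq_per_mol("ferrous_iron")

    d_so4 = _clip(baselines["sulfate"] - endpoint.sulfate, "sulfate", lab)
    e_so4 = mass_to_micromoles(
        Measurement("sulfate", d_so4, Unit.mg_per_g), geometry, MOLAR_MASS["SO4"]
    ) * eeq_per_mol("sulfide")

    e_ch4 = permil_to_micromoles(
        Measurement("ch4", endpoint.ch4, Unit.permil_headspace), geometry
    ) * eeq_per_mol("methane_acetoclastic")

    e_dechlor = 0.0
    for field_name, species in _PRODUCTS:
        conc = getattr(endpoint, field_name)
        if conc > 0:
            moles = mass_to_micromoles(
                Measurement(field_name, conc, Unit.ug_per_g),
                geometry,
                species.molar_mass,
            )
            e_dechlor += moles * dechlorination_eeq(ChlorophenolSpecies.PCP, species)

    return ElectronLedger(lab, e_fe, e_so4, e_dechlor, e_ch4)


def compute_ledgers(
    endpoints: list[IncubationEndpoint],
    geometry: BottleGeometry | None = None,
    baseline: str = "matched",
    include_sterile: bool = False,
) -> list[ElectronLedger]:
    """Ledgers for all biotic bottles, with per-amendment sterile baselines."""
    out = []
    for e in endpoints:
        if e.label.group == "sterile_abiotic" and not include_sterile:
            continue
        bl = compute_baselines(endpoints, e.label.amendment, baseline)
        out.append(compute_ledger(e, bl, geometry))
    return out


def ledgers_to_frame(ledgers: list[ElectronLedger]) -> pd.DataFrame:
    """Tidy DataFrame (one row per bottle) from a list of ledgers."""
    return pd.DataFrame(
        {
            "group": [l.label.group for l in ledgers],
            "amendment": [l.label.amendment for l in ledgers],
            "replicate": [l.label.replicate for l in ledgers],
            "e_fe_umol": [l.e_fe for l in ledgers],
            "e_so4_umol": [l.e_so4 for l in ledgers],
            "e_dechlor_umol": [l.e_dechlor for l in ledgers],
            "e_ch4_umol": [l.e_ch4 for l in ledgers],
            "e_total_umol": [l.e_total for l in ledgers],
        }
    )


def compact_letter_display(
    levels: list[str],
    means: dict[str, float],
    pairwise_p: dict[tuple[str, str], float],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Assign compact letters so that levels sharing a letter are not
    significantly different (p >= alpha) and levels with disjoint letters
    are (p < alpha).

    Implementation: letters are the maximal cliques of the
    "not-significantly-different" graph, ordered by descending group mean
    (the familiar 'a' on the largest mean).  Feasible exactly because the
    graph of pairwise non-differences is an interval-like graph for the
    handful of levels a treatment table holds; maximal cliques are found by
    subset enumeration.
    """
    order = sorted(levels, key=lambda l: -means[l])
    n = len(order)

    def ns(a: str, b: str) -> bool:
        p = pairwise_p.get((a, b), pairwise_p.get((b, a)))
        if p is None or np.isnan(p):
            return True  # unknown -> cannot claim a difference
        return p >= alpha

    cliques: list[set[str]] = []
    for size in range(n, 0, -1):
        for combo in itertools.combinations(order, size):
            s = set(combo)
            if any(s <= c for c in cliques):
                continue
            if all(ns(a, b) for a, b in itertools.combinations(combo, 2)):
                cliques.append(s)
    # order cliques by the best (largest) mean they contain
    cliques.sort(key=lambda c: min(order.index(l) for l in c))
    letters = {l: "" for l in levels}
    for i, c in enumerate(cliques):
        ch = chr(ord("a") + i)
        for l in order:
            if l in c:
                letters[l] += ch
    return letters


def summarize_groups(
    df: pd.DataFrame,
    value_columns: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Treatment-cell summaries with ANOVA and Tukey-HSD letters.

    ``df`` is tidy with columns ``group``, ``amendment``, ``replicate`` and
    numeric value columns (endpoints or ledger components).  Within each
    group, amendments are compared by one-way ANOVA; pairwise Tukey HSD
    p-values at ``alpha`` drive the compact letter display.  Cells with
    fewer than 2 replicates, or groups with zero between+within variance,
    report NA statistics and a single shared letter.
    """
    if value_columns is None:
        value_columns = [
            c
            for c in df.columns
            if c not in ("group", "amendment", "replicate")
            and pd.api.types.is_numeric_dtype(df[c])
        ]
    rows = []
    for (grp, col), sub in (
        (key, df[df["group"] == key[0]]) for key in
        itertools.product(df["group"].unique(), value_columns)
    ):
        cells = {
            am: sub.loc[sub["amendment"] == am, col].dropna().to_numpy()
            for am in sub["amendment"].unique()
        }
        cells = {am: v for am, v in cells.items() if len(v) > 0}
        levels = list(cells)
        means = {am: float(np.mean(v)) for am, v in cells.items()}
        sds = {am: float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
               for am, v in cells.items()}
        ns = {am: len(v) for am, v in cells.items()}

        f_stat = p_val = np.nan
        letters = {am: "a" for am in levels}
        enough = len(levels) >= 2 and all(n >= 2 for n in ns.values())
        pooled = np.concatenate(list(cells.values())) if levels else np.array([])
        degenerate = pooled.size == 0 or np.allclose(pooled, pooled.flat[0])
        if enough and not degenerate:
            f_stat, p_val = stats.f_oneway(*cells.values())
            res = stats.tukey_hsd(*cells.values())
            pw = {
                (levels[i], levels[j]): float(res.pvalue[i, j])
                for i in range(len(levels))
                for j in range(i + 1, len(levels))
            }
            letters = compact_letter_display(levels, means, pw, alpha)
        for am in levels:
            rows.append(
                {
                    "group": grp,
                    "variable": col,
                    "amendment": am,
                    "mean": means[am],
                    "sd": sds[am],
                    "n": ns[am],
                    "anova_F": float(f_stat) if np.isfinite(f_stat) else np.nan,
                    "anova_p": float(p_val) if np.isfinite(p_val) else np.nan,
                    "letters": letters[am],
                }
            )
    return pd.DataFrame(rows)
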