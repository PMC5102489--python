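"""Line-transect abundance and biomass indices with effort diagnostics.

Abundance is expressed as a kilometric index (KI): contacts per km walked,
or individuals per km for gregarious species (group sizes summed). The
biomass index is KI × species mean adult mass (kg/km), additive over species
for a community total. Effort sufficiency follows the truncation approach:
recompute KI from only the first d km of each survey and correlate, across
surveys, with the full-effort ("asymptotic") KI — for homogeneous Poisson
encounters that correlation is exactly √(d/L).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .errors import InvalidArgumentError, MissingTraitError, NoDataError


@dataclass
class TransectSurvey:
    """One site's survey: contacts plus effort and site covariates."""

    site: str
    total_km: float
    contacts: pd.DataFrame          # species, group_size, km_position
    hfi: float | None = None
    suitability: float | None = None

    def __post_init__(self) -> None:
        if self.total_km <= 0:
            raise InvalidArgumentError("transect length must be positive")
        if len(self.contacts) and (self.contacts["group_size"] < 1).any():
            raise InvalidArgumentError("group sizes must be >= 1")


def surveys_from_tables(contacts: pd.DataFrame,
                        site_table: pd.DataFrame) -> list[TransectSurvey]:
    """Assemble TransectSurvey objects from the flat CSV layout."""
    out = []
    for _, row in site_table.iterrows():
        sub = contacts[contacts["site"] == row["site"]]
        out.append(TransectSurvey(
            site=row["site"], total_km=float(row["total_km"]),
            contacts=sub.reset_index(drop=True),
            hfi=float(row["hfi"]) if "hfi" in row else None,
            suitability=float(row["suitability"]) if "suitability" in row else None))
    return out


def kilometric_index(survey: TransectSurvey, species: str,
                     traits: pd.DataFrame, max_km: float | None = None) -> float:
    """KI of one species: contacts (or individuals if gregarious) per km.

    ``max_km`` truncates the survey to its first ``max_km`` kilometres
    (capped at the survey length) for effort-sufficiency analyses.
    """
    trait = traits[traits["species"] == species]
    if trait.empty:
        raise MissingTraitError(species)
    gregarious = bool(trait["gregarious"].iloc[0])
    length = survey.total_km if max_km is None else min(max_km, survey.total_km)
    if length <= 0:
        raise InvalidArgumentError("effective transect length must be positive")
    sub = survey.contacts[survey.contacts["species"] == species]
    if max_km is not None:
        sub = sub[sub["km_position"] <= length]
    if gregarious:
        return float(sub["group_size"].sum()) / length
    return float(len(sub)) / length


def biomass_index(ki: float, adult_mass_kg: float) -> float:
    """Biomass index B = KI × mean adult mass (kg per km of transect)."""
    if ki < 0:
        raise InvalidArgumentError("KI must be >= 0")
    if adult_mass_kg <= 0:
        raise InvalidArgumentError("adult mass must be positive")
    return ki * adult_mass_kg


def ki_table(surveys: list[TransectSurvey], traits: pd.DataFrame) -> pd.DataFrame:
    """Per-site × species KI and biomass, with per-group community sums.

    Returns one row per site with columns ``ki_<species>``,
    ``biomass_<species>``, and per trait-group sums ``ki_<group>_total`` and
    ``biomass_<group>_total`` (the community abundance/biomass of that
    group), plus site covariates when present.
    """
    rows = []
    for sv in surveys:
        rec: dict = {"site": sv.site, "total_km": sv.total_km}
        if sv.hfi is not None:
            rec["hfi"] = sv.hfi
        if sv.suitability is not None:
            rec["suitability"] = sv.suitability
        for _, tr in traits.iterrows():
            ki = kilometric_index(sv, tr["species"], traits)
            rec[f"ki_{tr['species']}"] = ki
            rec[f"biomass_{tr['species']}"] = biomass_index(ki, tr["mass_kg"])
        for grp, sub in traits.groupby("group"):
            rec[f"ki_{grp}_total"] = sum(rec[f"ki_{s}"] for s in sub["species"])
            rec[f"biomass_{grp}_total"] = sum(rec[f"biomass_{s}"]
                                              for s in sub["species"])
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class EffortCurve:
    """Correlation between truncated-effort and full-effort KI, per truncation."""

    curve: pd.DataFrame            # truncation_km, r, n_surveys
    sufficient_km: float | None    # smallest d with r >= threshold
    threshold: float
    clipped_surveys: int           # surveys shorter than the largest truncation


def effort_sufficiency(surveys: list[TransectSurvey], species: str,
                       traits: pd.DataFrame, truncation_grid: np.ndarray,
                       threshold: float = 0.9, method: str = "pearson",
                       ) -> EffortCurve:
    """Effort needed for a stabilized KI, by the truncation-correlation rule.

    For each truncation distance d, KI is recomputed from the first d km of
    every survey and correlated across surveys with the full-effort KI; the
    sufficient effort is the smallest d whose correlation reaches
    ``threshold``. Surveys shorter than a truncation contribute their full
    length (flagged in ``clipped_surveys``).
    """
    if len(surveys) < 10:
        raise InvalidArgumentError("need at least 10 surveys")
    corr = pearsonr if method == "pearson" else spearmanr
    trait = traits[traits["species"] == species]
    if trait.empty:
        raise MissingTraitError(species)
    gregarious = bool(trait["gregarious"].iloc[0])
    # pre-extract sorted positions and cumulative weights per survey so each
    # truncation is a searchsorted, not a frame scan
    lengths = np.array([sv.total_km for sv in surveys])
    pos_w = []
    for sv in surveys:
        sub = sv.contacts[sv.contacts["species"] == species]
        p = sub["km_position"].to_numpy(dtype=float)
        w = (sub["group_size"].to_numpy(dtype=float) if gregarious
             else np.ones(p.size))
        order = np.argsort(p)
        pos_w.append((p[order], np.concatenate([[0.0], np.cumsum(w[order])])))
    full = np.array([cw[-1] for _, cw in pos_w]) / lengths
    if np.std(full) == 0:
        raise NoDataError("full-effort KI has zero variance across surveys")
    rows = []
    clipped = 0
    for d in np.asarray(truncation_grid, dtype=float):
        clipped = max(clipped, int(np.count_nonzero(lengths < d)))
        eff = np.minimum(d, lengths)
        trunc = np.array([cw[np.searchsorted(p, e, side="right")]
                          for (p, cw), e in zip(pos_w, eff)]) / eff
        if np.std(trunc) == 0:
            r = np.nan
        elif np.allclose(trunc, full):
            r = 1.0
        else:
            r = float(corr(trunc, full)[0])
        rows.append((float(d), r, len(surveys)))
    curve = pd.DataFrame(rows, columns=["truncation_km", "r", "n_surveys"])
    ok = curve[curve["r"] >= threshold]
    sufficient = float(ok["truncation_km"].iloc[0]) if len(ok) else None
    return EffortCurve(curve=curve, sufficient_km=sufficient,
                       threshold=threshold, clipped_surveys=clipped)


# Column layout expected from the published per-site supplementary table:
# one row per survey site with a human-footprint column and per-species
# kilometric abundances. Species columns are matched case-insensitively on
# genus_species fragments.
S1_MAMMALS = ("myoprocta", "dasyprocta", "mazama", "pecari", "tayassu")
S1_BIRDS = ("crax", "psophia")


def load_s1_table(path, hfi_column: str | None = None) -> pd.DataFrame:
    """Load the per-site survey table (xlsx) into a tidy frame.

    Returns one row per site with ``hfi``, ``ki_mammal_total`` and
    ``ki_bird_total`` columns: the summed kilometric abundances of the five
    target mammals and the two large terrestrial birds. Column matching is
    by genus-name fragment, so cosmetic header differences survive.
    """
    raw = pd.read_excel(path)
    cols = {c: str(c).strip().lower() for c in raw.columns}
    if hfi_column is None:
        hits = [c for c, lc in cols.items()
                if "footprint" in lc or lc in ("hfi", "hf")]
        if not hits:
            raise NoDataError("no human-footprint column found")
        hfi_column = hits[0]
    mam = [c for c, lc in cols.items() if any(g in lc for g in S1_MAMMALS)]
    brd = [c for c, lc in cols.items() if any(g in lc for g in S1_BIRDS)]
    if not mam or not brd:
        raise NoDataError("species abundance columns not found")
    num = raw.apply(pd.to_numeric, errors="coerce")
    out = pd.DataFrame({
        "hfi": num[hfi_column],
        "ki_mammal_total": num[mam].sum(axis=1),
        "ki_bird_total": num[brd].sum(axis=1),
    }).dropna()
    return out.reset_index(drop=True)
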