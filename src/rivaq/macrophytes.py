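"""Macrophyte ecological profiles, trophic scoring and groundwater influence.

Aquatic plant communities integrate two signals about the water that feeds
a wetland: its nutrient (trophic) level and its thermal stability.
Groundwater-fed habitats are thermally stable (low seasonal temperature
variability), so species confined to low temperature-variability sites are
read as groundwater-preferring, and species avoiding such sites as
intolerant of stenothermic water.

The workflow:

1. Sites are ranked by an environmental descriptor — relative standard
   deviation of monthly temperature (thermal axis), a combined phosphorus
   score, or mean ammonia — and split into *equilibrated* (equal-count)
   classes: 5 for temperature and phosphorus, 4 for ammonia.
2. For each species occurring in enough sites, mean abundance per class is
   computed; a mean-centred Levene test gates the class-difference test
   (one-way ANOVA when variances are homogeneous, Kruskal-Wallis
   otherwise).  Normalized per-class means form the species' ecological
   profile.
3. Phosphorus and ammonia profiles combine into a 4-class trophic profile
   (oligo-, meso-, eu-, hyper-eutrophic) through an ordered-quantile
   correspondence matrix.
4. A site relevé (Braun-Blanquet cover codes) is scored by summing
   code * profile over its species; the argmax class is the site's trophic
   level, and the difference between groundwater-preferring and
   stenothermy-intolerant species counts gives a groundwater-influence
   index mapped to four classes (null / low / intermediate / high).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RivaqError

TROPHIC_CLASSES = ["oligotrophic", "mesotrophic", "eutrophic", "hyper-eutrophic"]

THERMAL_GW = "groundwater_preferring"
THERMAL_INTOLERANT = "stenothermy_intolerant"
THERMAL_INDIFFERENT = "indifferent"

INFLUENCE_CLASSES = ["null", "low", "intermediate", "high"]

#: Braun-Blanquet cover-abundance codes -> numeric abundance
BB_NUMERIC = {"r": 0.1, "+": 0.5, "1": 1.0, "2": 2.0, "3": 3.0, "4": 4.0, "5": 5.0}

DEFAULT_ALPHA = 0.05
MIN_OCCURRENCE_SITES = 5


@dataclass
class EcologicalProfile:
    species: str
    weights: np.ndarray  # per-class affinity, >=0, sums to 1
    test: str  # "anova" | "kruskal" | "degenerate"
    p: float
    significant: bool
    n_sites: int
    thermal_category: str | None = None


@dataclass(frozen=True)
class TrophicAssessment:
    site_id: str
    class_scores: np.ndarray  # one score per TROPHIC_CLASSES entry
    assigned_class: str
    tied: bool
    n_species_scored: int
    n_species_skipped: int


@dataclass(frozen=True)
class GroundwaterInfluence:
    site_id: str
    index: int
    influence_class: str
    n_groundwater_preferring: int
    n_stenothermy_intolerant: int


# ---------------------------------------------------------------------------
# environmental descriptors and site classing

def relative_sd(series) -> float:
    """Coefficient of variation in percent: 100 * sample SD / mean."""
    arr = np.asarray(series, dtype=float)
    if arr.size < 2:
        raise RivaqError("relative_sd needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise RivaqError("undefined coefficient of variation: mean is zero")
    return float(100.0 * arr.std(ddof=1) / mean)


def equilibrated_classes(values, k: int) -> np.ndarray:
    """Split sites into k equal-count ordered classes (0 = lowest values).

    Class sizes differ by at most one when values are distinct.  Sites
    whose value ties a class boundary all fall into the *lower* class,
    which can unbalance counts — a documented consequence of the tie rule.
    """
    if k < 2:
        raise RivaqError("invalid class count: k must be >= 2")
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < k:
        raise RivaqError(f"need at least k={k} sites, got {n}")
    order = np.argsort(arr, kind="stable")
    prelim = np.empty(n, dtype=int)
    prelim[order] = (np.arange(n) * k) // n
    # ties share the lowest preliminary class among equal values
    labels = prelim.copy()
    for v in np.unique(arr):
        mask = arr == v
        labels[mask] = prelim[mask].min()
    return labels


def phosphorus_score(
    monthly_po4: dict[str, "pd.Series | np.ndarray | list"],
    substrate_totalp: dict[str, "pd.Series | np.ndarray | list"],
) -> pd.Series:
    """Combined per-site phosphorus score.

    score = mean(log10 monthly PO4) + zscore_across_sites(log10 mean total P)

    Zero concentrations are shifted by half the smallest positive value of
    the same variable before the log (a standard detection-limit device).
    Substrate replicates are averaged before the log transform.
    """
    sites = sorted(monthly_po4)
    if sorted(substrate_totalp) != sites:
        raise RivaqError("PO4 and total-P site sets differ")

    def _shifted(values_by_site):
        allv = np.concatenate([np.asarray(v, dtype=float) for v in values_by_site.values()])
        if (allv < 0).any():
            raise RivaqError("negative concentration")
        pos = allv[allv > 0]
        if pos.size == 0:
            raise RivaqError("no phosphorus signal: all values are zero")
        shift = pos.min() / 2.0
        return {
            s: np.where(np.asarray(v, dtype=float) > 0, np.asarray(v, dtype=float),
                        shift)
            for s, v in values_by_site.items()
        }

    po4 = _shifted(monthly_po4)
    totp = _shifted(substrate_totalp)
    log_po4_mean = np.array([np.log10(po4[s]).mean() for s in sites])
    log_totp = np.array([math.log10(np.mean(totp[s])) for s in sites])
    sd = log_totp.std(ddof=1) if len(sites) > 1 else 0.0
    z = (log_totp - log_totp.mean()) / sd if sd > 0 else np.zeros_like(log_totp)
    return pd.Series(log_po4_mean + z, index=sites, name="phosphorus_score")


# ---------------------------------------------------------------------------
# species ecological profiles

def species_class_response(
    abundance: pd.DataFrame,
    classes,
    alpha: float = DEFAULT_ALPHA,
    min_sites: int = MIN_OCCURRENCE_SITES,
) -> tuple[dict[str, EcologicalProfile], list[str]]:
    """Per-species class-response profiles over an environmental classing.

    ``abundance`` is a site x species table of numeric abundances (zeros
    for absences); ``classes`` maps each site (row) to an integer class
    label 0..k-1.  Species present in fewer than ``min_sites`` sites are
    excluded and listed in the returned second element.

    A mean-centred Levene test on the per-class abundance groups gates the
    class-difference test: one-way ANOVA when variances are homogeneous
    (Levene p >= alpha), Kruskal-Wallis otherwise.  The profile weights are
    the per-class mean abundances normalized to sum 1.
    """
    classes = np.asarray(classes, dtype=int)
    if classes.shape[0] != abundance.shape[0]:
        raise RivaqError("classes must label every site (row) of abundance")
    k = classes.max() + 1
    profiles: dict[str, EcologicalProfile] = {}
    excluded: list[str] = []
    for sp in abundance.columns:
        col = abundance[sp].to_numpy(dtype=float)
        n_occ = int((col > 0).sum())
        if n_occ < min_sites:
            excluded.append(sp)
            continue
        groups = [col[classes == c] for c in range(k)]
        means = np.array([g.mean() if g.size else 0.0 for g in groups])
        total = means.sum()
        weights = means / total if total > 0 else np.full(k, 1.0 / k)
        testable = [g for g in groups if g.size >= 2]
        if len(testable) < 2 or np.ptp(col) == 0:
            profiles[sp] = EcologicalProfile(sp, weights, "degenerate", float("nan"),
                                             False, n_occ)
            continue
        try:
            _, p_lev = stats.levene(*testable, center="mean")
        except ValueError:
            p_lev = float("nan")
        if math.isnan(p_lev) or p_lev >= alpha:
            test = "anova"
            _, p = stats.f_oneway(*testable)
        else:
            test = "kruskal"
            _, p = stats.kruskal(*testable)
        p = float(p)
        profiles[sp] = EcologicalProfile(
            sp, weights, test, p, bool(p < alpha), n_occ
        )
    return profiles, excluded


def thermal_category(profile: EcologicalProfile, k: int = 5) -> str:
    """Thermal habit of a species from its temperature-variability profile.

    Classes are ordered by increasing temperature variability, so a
    significant profile peaking in the two most stable classes marks a
    groundwater-preferring species, one peaking in the two most variable
    classes a stenothermy-intolerant species; everything else (including
    non-significant profiles) is indifferent.
    """
    if not profile.significant:
        return THERMAL_INDIFFERENT
    peak = int(np.argmax(profile.weights))
    if peak <= 1:
        return THERMAL_GW
    if peak >= k - 2:
        return THERMAL_INTOLERANT
    return THERMAL_INDIFFERENT


def quantile_correspondence(k_from: int, k_to: int) -> np.ndarray:
    """Row-stochastic matrix mapping k_from ordered classes onto k_to.

    Class j of the source covers the quantile interval [j/k_from,
    (j+1)/k_from); its weight is spread over the target classes by
    interval overlap.  This is the default 5-class -> 4-class trophic
    correspondence; rows sum to 1.
    """
    M = np.zeros((k_from, k_to))
    for j in range(k_from):
        lo, hi = j / k_from, (j + 1) / k_from
        for c in range(k_to):
            clo, chi = c / k_to, (c + 1) / k_to
            M[j, c] = max(0.0, min(hi, chi) - max(lo, clo)) * k_from
    return M


def combine_trophic_profile(
    p_profile: np.ndarray | None,
    n_profile: np.ndarray | None,
    mapping: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Merge phosphorus (5-class) and ammonia (4-class) affinity profiles
    into one 4-class trophic profile.

    The phosphorus profile is projected onto 4 classes with ``mapping``
    (default: ordered-quantile correspondence), averaged with the ammonia
    profile and renormalized.  When only one profile exists it passes
    through alone; the returned flag is True when both were present.
    """
    if p_profile is None and n_profile is None:
        raise RivaqError("no trophic information for species")
    if mapping is None:
        mapping = quantile_correspondence(5, 4)
    parts = []
    if p_profile is not None:
        parts.append(np.asarray(p_profile, dtype=float) @ mapping)
    if n_profile is not None:
        parts.append(np.asarray(n_profile, dtype=float))
    combined = np.mean(parts, axis=0)
    total = combined.sum()
    combined = combined / total if total > 0 else np.full(4, 0.25)
    return combined, len(parts) == 2


# ---------------------------------------------------------------------------
# site scoring

def bb_to_numeric(code, table: dict[str, float] | None = None) -> float:
    table = table or BB_NUMERIC
    key = str(code).strip()
    if key not in table:
        raise RivaqError(f"unknown Braun-Blanquet code {code!r}")
    return table[key]


def site_trophic_level(
    releve: dict[str, str],
    trophic_profiles: dict[str, np.ndarray],
    site_id: str = "",
    bb_table: dict[str, float] | None = None,
) -> TrophicAssessment:
    """Score one relevé into the four trophic classes.

    Each species contributes its numeric Braun-Blanquet abundance times its
    4-class trophic profile; class scores are the sums and the assigned
    class is the argmax.  Ties resolve toward the more eutrophic class and
    are flagged.  Species without a profile are skipped (counted).
    """
    scores = np.zeros(len(TROPHIC_CLASSES))
    scored = skipped = 0
    for sp, code in releve.items():
        prof = trophic_profiles.get(sp)
        if prof is None:
            skipped += 1
            continue
        scores += bb_to_numeric(code, bb_table) * np.asarray(prof, dtype=float)
        scored += 1
    if scored == 0:
        raise RivaqError(f"unscorable relevé: no profiled species at {site_id!r}")
    best = float(scores.max())
    winners = np.flatnonzero(np.isclose(scores, best, rtol=0, atol=1e-12))
    assigned = int(winners[-1])  # ties -> more eutrophic
    return TrophicAssessment(
        site_id, scores, TROPHIC_CLASSES[assigned], len(winners) > 1, scored, skipped
    )


def influence_class(index: int) -> str:
    """Map a groundwater-influence index to its class.

    0 -> null; 1-4 -> low; 5-9 -> intermediate; >9 -> high.  Index value 4
    is assigned to 'low' (the published bounds leave it unassigned); the
    convention is echoed in outputs.
    """
    if index <= 0:
        return "null"
    if index <= 4:
        return "low"
    if index <= 9:
        return "intermediate"
    return "high"


# ---------------------------------------------------------------------------
# full pipeline over a set of wetlands

def abundance_matrix(releves: dict[str, dict[str, str]],
                     bb_table: dict[str, float] | None = None) -> pd.DataFrame:
    """Site x species numeric-abundance table from Braun-Blanquet relevés."""
    sites = sorted(releves)
    species = sorted({sp for rel in releves.values() for sp in rel})
    mat = pd.DataFrame(0.0, index=sites, columns=species)
    for site, rel in releves.items():
        for sp, code in rel.items():
            mat.loc[site, sp] = bb_to_numeric(code, bb_table)
    return mat


def profile_community(
    environment: dict,
    releves: dict[str, dict[str, str]],
    alpha: float = DEFAULT_ALPHA,
    min_sites: int = MIN_OCCURRENCE_SITES,
) -> dict:
    """Derive all species profiles from site environments and relevés.

    ``environment`` maps variable names (``temperature``, ``po4``, ``nh3``,
    ``substrate_totalp``) to per-site series.  Returns a dict with the raw
    thermal / phosphorus / ammonia profiles, the combined 4-class trophic
    profiles, the per-species thermal categories, and the site classings
    used, so every downstream verdict is auditable.
    """
    abund = abundance_matrix(releves)
    sites = list(abund.index)

    temp_cv = np.array([relative_sd(environment["temperature"][s]) for s in sites])
    thermal_classes = equilibrated_classes(temp_cv, 5)

    p_score = phosphorus_score(
        {s: environment["po4"][s] for s in sites},
        {s: environment["substrate_totalp"][s] for s in sites},
    ).loc[sites]
    p_classes = equilibrated_classes(p_score.to_numpy(), 5)

    nh3_mean = np.array([np.mean(environment["nh3"][s]) for s in sites])
    n_classes = equilibrated_classes(nh3_mean, 4)

    thermal_prof, _ = species_class_response(abund, thermal_classes, alpha, min_sites)
    p_prof, _ = species_class_response(abund, p_classes, alpha, min_sites)
    n_prof, excluded = species_class_response(abund, n_classes, alpha, min_sites)

    thermal_categories = {
        sp: thermal_category(prof) for sp, prof in thermal_prof.items()
    }
    trophic: dict[str, np.ndarray] = {}
    for sp in abund.columns:
        pw = p_prof[sp].weights if sp in p_prof else None
        nw = n_prof[sp].weights if sp in n_prof else None
        if pw is None and nw is None:
            continue
        trophic[sp], _both = combine_trophic_profile(pw, nw)
    return {
        "thermal_profiles": thermal_prof,
        "phosphorus_profiles": p_prof,
        "ammonia_profiles": n_prof,
        "trophic_profiles": trophic,
        "thermal_categories": thermal_categories,
        "site_classes": pd.DataFrame(
            {
                "thermal": thermal_classes,
                "phosphorus": p_classes,
                "ammonia": n_classes,
            },
            index=sites,
        ),
        "excluded_species": excluded,
    }


def assess_sites(
    releves: dict[str, dict[str, str]],
    trophic_profiles: dict[str, np.ndarray],
    thermal_categories: dict[str, str],
) -> tuple[dict[str, TrophicAssessment], dict[str, GroundwaterInfluence]]:
    """Score every relevé: trophic level and groundwater influence."""
    trophic, influence = {}, {}
    for site, rel in sorted(releves.items()):
        try:
            trophic[site] = site_trophic_level(rel, trophic_profiles, site)
        except RivaqError:
            pass  # unscorable site: no profiled species
        influence[site] = groundwater_influence(rel, thermal_categories, site)
    return trophic, influence


def groundwater_influence(
    releve: dict[str, str],
    thermal_categories: dict[str, str],
    site_id: str = "",
) -> GroundwaterInfluence:
    """Groundwater-influence index of a site from its species list.

    index = (# groundwater-preferring species present)
          − (# stenothermy-intolerant species present), floored at 0,
    so a larger index means stronger groundwater influence.
    """
    present = [sp for sp, code in releve.items()]
    n_gw = sum(1 for sp in present if thermal_categories.get(sp) == THERMAL_GW)
    n_int = sum(
        1 for sp in present if thermal_categories.get(sp) == THERMAL_INTOLERANT
    )
    index = max(n_gw - n_int, 0)
    return GroundwaterInfluence(site_id, index, influence_class(index), n_gw, n_int)
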