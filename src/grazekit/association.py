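"""Genotype-behaviour association: encoding, correlations, model selection,
marginal means, Benjamini-Hochberg post-hoc with compact letter display.

The analysis follows the two-step protocol used for herd GPS studies:

1. For each behaviour, twelve candidate random-intercept structures (all
   containing cow identity, since daily records are repeated measures) are
   fitted by ML to the intercept-only model and ranked; the "best
   compromise" is resolved deterministically (AIC within 2 of the best ->
   fewest parameters -> lowest BIC -> enumeration order), followed by a
   likelihood-ratio simplification pass at alpha = 0.05.
2. With the chosen random structure, the genetic predictor (presence/absence
   of an allele, or the full genotype) is always retained; cow age class is
   kept only when the ML likelihood-ratio comparison favours it at 0.05.
   Final models are refitted by REML.

Gaussian LMMs are used for log-transformed behaviours; 0-1 bounded
behaviours get a logit-link PQL fit (or an LMM on the logit-transformed
response, selectable).  Fixed effects are tested with Satterthwaite's
approximation; pairwise marginal-mean contrasts are adjusted with
Benjamini-Hochberg and summarised with compact letters.

Multiple testing across the eleven behaviours is deliberately NOT adjusted;
interpret the behaviour-level p-values accordingly.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .behaviours import BEHAVIOURS
from .lmm import LMMFit, fit_lmm, fit_pql_logit, lrt

log = logging.getLogger(__name__)

ALLELES = ("A", "B", "C")

#: behaviours modelled on the log scale (Gaussian LMM)
LOG_BEHAVIOURS = ("ho_dist", "ve_dist", "three_d_dist", "ele_range",
                  "ele_gain", "hr_mcp", "sp_tortuosity")
#: behaviours modelled on the 0-1 scale (logit link); slope85 is percent/100
BOUNDED_BEHAVIOURS = ("rel_ele", "rel_ele85", "rel_ele_range", "slope85")


class GenotypeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genotype encoding and frequency accounting
# ---------------------------------------------------------------------------

def encode_genotypes(metadata: pd.DataFrame, rare_freq: float = 0.05):
    """Presence/absence coding plus the frequency report and rare exclusions.

    Returns ``(records, report)``: ``records`` is metadata with boolean
    ``has_A/has_B/has_C`` columns and an ``excluded`` flag for cows whose
    genotype's overall frequency is below ``rare_freq``; ``report`` holds
    per-farm and overall counts with rounded percentage frequencies and the
    excluded genotype set.
    """
    rec = metadata.copy()
    geno = rec["genotype"].astype(str)
    bad = geno[~geno.str.fullmatch(r"[ABC]{2}")]
    if len(bad):
        raise GenotypeError(f"invalid genotype string(s): {sorted(bad.unique())}")
    for al in ALLELES:
        rec[f"has_{al}"] = geno.str.contains(al)
    counts = geno.value_counts().sort_index()
    total = int(counts.sum())
    freqs = counts / total
    pct = (100.0 * freqs).round().astype(int)
    per_farm = (
        rec.groupby(["farm", "genotype"]).size().unstack(fill_value=0).sort_index()
        if "farm" in rec.columns else None
    )
    excluded = sorted(freqs[freqs < rare_freq].index)
    rec["excluded"] = geno.isin(excluded)
    report = {
        "counts": counts.to_dict(),
        "percent": pct.to_dict(),
        "per_farm_counts": per_farm,
        "excluded_genotypes": excluded,
        "n_total": total,
        "n_analysed": int((~rec["excluded"]).sum()),
        "rare_threshold": rare_freq,
    }
    log.info("genotype accounting: %d cows, excluded %s (rare < %g), %d analysed",
             total, excluded or "none", rare_freq, report["n_analysed"])
    return rec, report


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def transform_responses(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``resp_<behaviour>`` columns on each behaviour's modelling scale.

    Log behaviours get their natural log (non-positive rows dropped with a
    logged count); bounded behaviours keep the 0-1 value (slope85 percent is
    divided by 100) -- the link function is applied at fit time.
    """
    out = table.copy()
    n_dropped = 0
    drop_mask = np.zeros(len(out), dtype=bool)
    for b in LOG_BEHAVIOURS:
        if b not in out.columns:
            continue
        v = out[b].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"resp_{b}"] = np.where(v > 0, np.log(v), np.nan)
        nonpos = (v <= 0) & np.isfinite(v)
        if nonpos.any():
            n_dropped += int(nonpos.sum())
            drop_mask |= nonpos
    for b in BOUNDED_BEHAVIOURS:
        if b not in out.columns:
            continue
        v = out[b].to_numpy(float)
        if b == "slope85":
            v = v / 100.0
        out[f"resp_{b}"] = np.clip(v, 0.0, 1.0)
    if n_dropped:
        log.warning("dropped %d rows with non-positive values under log transform",
                    n_dropped)
    return out


def back_transform(eta, se, link: str):
    """(mean, se) on the measured scale from a link-scale estimate (delta method)."""
    eta = np.asarray(eta, float)
    se = np.asarray(se, float)
    if link == "log":
        m = np.exp(eta)
        return m, m * se
    if link == "logit":
        m = special.expit(eta)
        return m, m * (1 - m) * se
    if link == "identity":
        return eta, se
    raise ValueError(f"unknown link {link!r}")


def link_for(behaviour: str) -> str:
    if behaviour in LOG_BEHAVIOURS:
        return "log"
    if behaviour in BOUNDED_BEHAVIOURS:
        return "logit"
    return "identity"


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_matrix(profiles: pd.DataFrame, behaviours=BEHAVIOURS):
    """Pairwise-complete Pearson correlations between per-cow behaviour means.

    Returns ``(pairs, matrix)``: a tidy table of (behaviour_1, behaviour_2,
    r, p, n, stars) for the lower triangle, and the symmetric r matrix
    (diagonal 1).
    """
    cols = [b for b in behaviours if b in profiles.columns]
    m = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    rows = []
    for i, b1 in enumerate(cols):
        for b2 in cols[i + 1:]:
            sub = profiles[[b1, b2]].dropna()
            n = len(sub)
            if n < 3 or sub[b1].nunique() < 2 or sub[b2].nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(sub[b1], sub[b2])
            m.loc[b1, b2] = m.loc[b2, b1] = r
            rows.append({"behaviour_1": b1, "behaviour_2": b2, "r": r, "p": p,
                         "n": n, "stars": _stars(p) if np.isfinite(p) else ""})
    return pd.DataFrame(rows), m


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Design:
    """Treatment-coded fixed-effects design with a reference grid."""

    terms: list          # [(column, levels)] categorical terms after intercept
    xnames: list

    @classmethod
    def from_terms(cls, data: pd.DataFrame, columns: list) -> "Design":
        terms = []
        xnames = ["(Intercept)"]
        for col in columns:
            levels = sorted(pd.unique(data[col]))
            terms.append((col, levels))
            xnames += [f"{col}[{lv}]" for lv in levels[1:]]
        return cls(terms=terms, xnames=xnames)

    def matrix(self, data: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(data))]
        for col, levels in self.terms:
            v = data[col].to_numpy()
            for lv in levels[1:]:
                cols.append((v == lv).astype(float))
        return np.column_stack(cols)

    def grid(self) -> pd.DataFrame:
        """Full cross of all term levels (the emmeans reference grid)."""
        if not self.terms:
            return pd.DataFrame(index=[0])
        combos = list(itertools.product(*[lv for _, lv in self.terms]))
        return pd.DataFrame(combos, columns=[c for c, _ in self.terms])


# ---------------------------------------------------------------------------
# random structure enumeration and selection
# ---------------------------------------------------------------------------

#: the twelve candidate random structures beyond the always-present cow_id.
#: ``farm_year`` denotes the farm-within-year interaction grouping.
RANDOM_STRUCTURES = (
    ("RF1", ()),
    ("RF2", ("farm",)),
    ("RF3", ("year",)),
    ("RF4", ("year", "farm_year")),
    ("RF5", ("farm", "year")),
    ("RF6", ("mob",)),
    ("RF7", ("sire",)),
    ("RF8", ("mob", "sire")),
    ("RF9", ("farm", "sire")),
    ("RF10", ("genotype",)),
    ("RF11", ("mob", "genotype")),
    ("RF12", ("farm", "year", "farm_year")),
)


def enumerate_random_structures():
    """The default list of 12 random-factor combinations (cow_id implied)."""
    return list(RANDOM_STRUCTURES)


def _random_factors(data: pd.DataFrame, terms) -> dict:
    factors = {"cow_id": data["cow_id"].to_numpy()}
    for t in terms:
        if t == "farm_year":
            codes = data["farm"].astype(str) + ":" + data["year"].astype(str)
        else:
            codes = data[t]
        factors[t] = codes.to_numpy()
    return factors


def _fit(data, response, fixed_cols, random_terms, link, reml, glmm_mode="pql"):
    design = Design.from_terms(data, fixed_cols)
    X = design.matrix(data)
    y = data[response].to_numpy(float)
    factors = _random_factors(data, random_terms)
    if link == "logit" and glmm_mode == "pql":
        fit = fit_pql_logit(y, X, factors, reml=reml, xnames=design.xnames)
    elif link == "logit":
        fit = fit_lmm(special.logit(np.clip(y, 1e-4, 1 - 1e-4)), X, factors,
                      reml=reml, xnames=design.xnames)
        fit.link = "logit"
    else:
        fit = fit_lmm(y, X, factors, reml=reml, xnames=design.xnames)
        fit.link = "log" if link == "log" else "identity"
    fit.design = design
    return fit


def select_random_structure(data: pd.DataFrame, response: str, link: str = "identity",
                            candidates=None, alpha: float = 0.05,
                            glmm_mode: str = "pql"):
    """Choose the random structure for one behaviour; returns (terms, ranking).

    Candidates are fitted by ML to the intercept-only model.  The winner is
    resolved by the deterministic cascade (AIC within 2 -> fewest model
    parameters -> lowest BIC -> enumeration order); a final simplification
    pass replaces the winner by the smallest nested candidate that an ML
    likelihood-ratio test cannot reject at ``alpha``.
    """
    candidates = list(candidates or enumerate_random_structures())
    fits = {}
    rows = []
    for order, (name, terms) in enumerate(candidates):
        try:
            fit = _fit(data, response, [], terms, link, reml=False, glmm_mode=glmm_mode)
        except Exception as exc:  # non-convergence / singular factor
            log.warning("random structure %s (%s) skipped: %s", name, terms, exc)
            continue
        if not fit.converged:
            log.warning("random structure %s did not converge; skipped", name)
            continue
        fits[name] = fit
        rows.append({"structure": name, "terms": "+".join(terms) or "(cow only)",
                     "order": order, "df": fit.df_model, "logLik": fit.loglik,
                     "AIC": fit.aic, "BIC": fit.bic, "singular": fit.singular})
    if not rows:
        raise RuntimeError(f"no random-structure candidate converged for {response}")
    ranking = pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
    best_aic = ranking["AIC"].min()
    short = ranking[ranking["AIC"] <= best_aic + 2.0]
    short = short.sort_values(["df", "BIC", "order"], kind="mergesort")
    chosen = short.iloc[0]["structure"]
    # simplification: smallest nested candidate the LRT cannot reject
    terms_of = dict(candidates)
    chosen_terms = set(terms_of[chosen])
    nested = sorted(
        (n for n in fits if set(terms_of[n]) < chosen_terms),
        key=lambda n: (fits[n].df_model, ranking.set_index("structure").loc[n, "order"]),
    )
    for n in nested:
        _, _, p = lrt(fits[chosen], fits[n])
        if p >= alpha:
            log.info("%s: simplified %s -> %s (LRT p = %.3f)", response, chosen, n, p)
            chosen = n
            chosen_terms = set(terms_of[n])
    return terms_of[chosen], ranking


def select_fixed_structure(data: pd.DataFrame, response: str, random_terms,
                           genetic_col: str, link: str = "identity",
                           alpha: float = 0.05, glmm_mode: str = "pql"):
    """Decide whether cow age class joins the genetic predictor.

    Returns ``(fixed_cols, age_p)``: the ML likelihood-ratio p-value for
    adding age class, and the fixed-effect column list of the final model
    (the genetic term is always retained).
    """
    with_age = _fit(data, response, [genetic_col, "age_class"], random_terms,
                    link, reml=False, glmm_mode=glmm_mode)
    without = _fit(data, response, [genetic_col], random_terms,
                   link, reml=False, glmm_mode=glmm_mode)
    stat = max(0.0, 2.0 * (with_age.loglik - without.loglik))
    df = with_age.p - without.p
    age_p = float(stats.chi2.sf(stat, df))
    cols = [genetic_col] + (["age_class"] if age_p < alpha else [])
    return cols, age_p


def fit_mixed_model(data: pd.DataFrame, response: str, fixed_cols, random_terms,
                    link: str = "identity", reml: bool = True,
                    glmm_mode: str = "pql") -> LMMFit:
    """Final-model fit (REML by default) with the chosen structures."""
    return _fit(data, response, fixed_cols, random_terms, link, reml, glmm_mode)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def residual_diagnostics(fit: LMMFit, limit: float = 3.0,
                         max_frac: float = 0.05) -> dict:
    """Scaled residuals vs fitted; pass iff <= ``max_frac`` beyond +-limit."""
    resid = fit.scaled_residuals()
    frac = float(np.mean(np.abs(resid) > limit)) if len(resid) else 0.0
    return {
        "fraction_beyond": frac,
        "passed": frac <= max_frac,
        "residuals": resid,
        "fitted": fit.fitted(),
        "limit": limit,
    }


# ---------------------------------------------------------------------------
# marginal means
# ---------------------------------------------------------------------------

def marginal_means(fit: LMMFit, grouping) -> pd.DataFrame:
    """Estimated marginal means over ``grouping`` factor(s).

    The reference grid is the full cross of the model's categorical fixed
    factors; cells are averaged with equal weights over the levels of the
    non-grouping factors.  Returns link-scale estimates with Satterthwaite
    df and back-transformed means/SEs (delta method).
    """
    if isinstance(grouping, str):
        grouping = [grouping]
    grouping = list(grouping or [])
    design: Design = fit.design
    grid = design.grid()
    Xg = design.matrix(grid) if len(grid.columns) else np.ones((1, fit.p))
    if not grouping:  # overall marginal mean across the whole grid
        c = Xg.mean(axis=0)
        est, se, df, _, _ = fit.contrast(c)
        mean_bt, se_bt = back_transform(est, se, fit.link)
        return pd.DataFrame([{"emm_link": est, "se_link": se, "df": df,
                              "mean": float(mean_bt), "se": float(se_bt),
                              "_c": c}])
    missing = [g for g in grouping if g not in grid.columns]
    if missing:
        raise ValueError(f"grouping factor(s) {missing} are not fixed factors "
                         f"of this model")
    rows = []
    for key, sub in grid.groupby(grouping, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        c = Xg[sub.index].mean(axis=0)
        est, se, df, _, _ = fit.contrast(c)
        mean_bt, se_bt = back_transform(est, se, fit.link)
        row = dict(zip(grouping, key))
        row.update({"emm_link": est, "se_link": se, "df": df,
                    "mean": float(mean_bt), "se": float(se_bt), "_c": c})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg and compact letters
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def compact_letters(groups, sig_pairs) -> dict:
    """Compact letter display by insert-and-absorb.

    ``sig_pairs`` is an iterable of (g1, g2) pairs that differ significantly.
    Two groups share a letter iff their pair is not in ``sig_pairs``.
    """
    groups = list(groups)
    classes = [set(groups)]
    for g1, g2 in sig_pairs:
        new = []
        for cl in classes:
            if g1 in cl and g2 in cl:
                new.append(cl - {g1})
                new.append(cl - {g2})
            else:
                new.append(cl)
        # absorb: keep distinct maximal classes only
        classes = []
        for cl in new:
            if cl and not any(cl < other for other in new) and cl not in classes:
                classes.append(cl)
    # stable letter order: by first member in group order
    def class_key(cl):
        return min(groups.index(g) for g in cl)

    classes.sort(key=class_key)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, cl in enumerate(classes):
        for g in groups:
            if g in cl:
                letters[g] += alphabet[i % 26]
    return letters


def posthoc_bh(fit: LMMFit, mm: pd.DataFrame, grouping, alpha: float = 0.05):
    """All pairwise marginal-mean contrasts, BH-adjusted, with letters.

    Returns ``(pairs, letters)``; contrasts are tested on the link scale
    with Satterthwaite df.
    """
    if isinstance(grouping, str):
        grouping = [grouping]
    labels = [
        "/".join(str(v) for v in row) for row in mm[grouping].itertuples(index=False)
    ]
    rows = []
    for i, j in itertools.combinations(range(len(mm)), 2):
        c = mm.iloc[i]["_c"] - mm.iloc[j]["_c"]
        est, se, df, t, p = fit.contrast(c)
        rows.append({"group_1": labels[i], "group_2": labels[j],
                     "estimate": est, "se": se, "df": df, "t": t, "p_raw": p})
    pairs = pd.DataFrame(rows)
    if len(pairs):
        pairs["p_adj"] = bh_adjust(pairs["p_raw"].to_numpy())
        sig = [(r.group_1, r.group_2) for r in pairs.itertuples() if r.p_adj < alpha]
    else:
        pairs["p_adj"] = []
        sig = []
    letters = compact_letters(labels, sig)
    return pairs, letters


# ---------------------------------------------------------------------------
# full suite
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BehaviourResult:
    behaviour: str
    link: str
    random_terms: tuple
    ranking: pd.DataFrame
    age_p: float
    age_included: bool
    variants: pd.DataFrame            # per-allele presence EMM, SE, p
    genotype_anova_p: float
    genotype_emm: pd.DataFrame | None
    posthoc: pd.DataFrame | None
    letters: dict | None
    diagnostics: dict


def run_association_suite(modelling: pd.DataFrame, alpha: float = 0.05,
                          glmm_mode: str = "pql", behaviours=BEHAVIOURS,
                          candidates=None) -> dict:
    """Variant-presence and genotype models for every behaviour.

    ``modelling`` is the daily-level table of retained cow-days joined to
    metadata with ``has_A/has_B/has_C`` columns, rare genotypes excluded and
    ``resp_<behaviour>`` columns added by :func:`transform_responses`.
    Returns ``{behaviour: BehaviourResult}``.
    """
    if modelling["genotype"].nunique() < 2:
        raise ValueError("need at least 2 genotype groups after rare exclusion")
    results = {}
    for b in behaviours:
        col = f"resp_{b}"
        if col not in modelling.columns:
            continue
        data = modelling.dropna(subset=[col]).reset_index(drop=True)
        if data.empty:
            log.warning("behaviour %s has no usable values; skipped", b)
            continue
        link = link_for(b)
        rnd, ranking = select_random_structure(
            data, col, link, candidates=candidates, alpha=alpha, glmm_mode=glmm_mode)
        if "genotype" in rnd:
            # genotype cannot stay random once it is the fixed predictor
            # under test: the random intercept would absorb the effect
            log.info("%s: dropping genotype from random terms for the "
                     "fixed-effect stage", b)
            rnd = tuple(t for t in rnd if t != "genotype")
        # variant presence/absence (dominance) models
        var_rows = []
        age_p_geno = None
        for al in ALLELES:
            gcol = f"has_{al}"
            if data[gcol].nunique() < 2:
                log.warning("%s: allele %s has no contrast; skipped", b, al)
                continue
            fixed, age_p = select_fixed_structure(
                data, col, rnd, gcol, link, alpha, glmm_mode)
            fit = fit_mixed_model(data, col, fixed, rnd, link, True, glmm_mode)
            jpres = fit.xnames.index(f"{gcol}[True]")
            c = np.zeros(fit.p)
            c[jpres] = 1.0
            _, _, _, _, p_var = fit.contrast(c)
            mm = marginal_means(fit, gcol)
            pres = mm[mm[gcol] == True].iloc[0]  # noqa: E712
            var_rows.append({"variant": al, "age_p": age_p,
                             "age_included": "age_class" in fixed,
                             "mean": pres["mean"], "se": pres["se"],
                             "p": p_var})
        variants = pd.DataFrame(var_rows)
        # genotype model
        fixed_g, age_p_geno = select_fixed_structure(
            data, col, rnd, "genotype", link, alpha, glmm_mode)
        fit_g = fit_mixed_model(data, col, fixed_g, rnd, link, True, glmm_mode)
        ml_with = _fit(data, col, fixed_g, rnd, link, False, glmm_mode)
        ml_without = _fit(data, col, [c for c in fixed_g if c != "genotype"],
                          rnd, link, False, glmm_mode)
        stat = max(0.0, 2.0 * (ml_with.loglik - ml_without.loglik))
        geno_p = float(stats.chi2.sf(stat, ml_with.p - ml_without.p))
        diag = residual_diagnostics(fit_g)
        posthoc = letters = genotype_emm = None
        if geno_p < alpha and "age_class" in fixed_g:
            genotype_emm = marginal_means(fit_g, ["genotype", "age_class"])
            posthoc, letters = posthoc_bh(fit_g, genotype_emm,
                                          ["genotype", "age_class"], alpha)
        elif geno_p < alpha:
            genotype_emm = marginal_means(fit_g, "genotype")
            posthoc, letters = posthoc_bh(fit_g, genotype_emm, "genotype", alpha)
        results[b] = BehaviourResult(
            behaviour=b, link=link, random_terms=tuple(rnd), ranking=ranking,
            age_p=age_p_geno, age_included="age_class" in fixed_g,
            variants=variants, genotype_anova_p=geno_p,
            genotype_emm=genotype_emm, posthoc=posthoc, letters=letters,
            diagnostics={k: diag[k] for k in ("fraction_beyond", "passed")},
        )
        log.info("%s: random=%s age_p=%.3g genotype_p=%.3g", b, rnd,
                 age_p_geno, geno_p)
    return results
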