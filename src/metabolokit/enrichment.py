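"""Set-level functional analysis.

Two families are provided: functional class scoring (FCS), which
aggregates entity-level statistics or p-values over an annotation set
without any significance cutoff (Fisher's combined probability,
Stouffer's Z, Reporter-features Z with background standardization,
median, mean) with entity-permutation significance; and
overrepresentation analysis (ORA), a hypergeometric test of a selected
entity list against a universe, with Fisher combination across node
types for heterogeneous networks.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_data import AnnotationSet
from .stats import adjust_bh

__all__ = [
    "combine_pvalues",
    "fcs_enrich",
    "ora_hypergeometric",
    "multitype_ora",
    "term_frequencies",
]

_EPS = 1e-15

FCS_METHODS = ("fisher", "stouffer", "reporter", "median", "mean")


class EnrichmentError(ValueError):
    pass


def _clip_p(p: np.ndarray) -> np.ndarray:
    if ((p <= 0) | (p >= 1)).any():
        warnings.warn("p-values at 0 or 1 clipped to the open interval")
    return np.clip(p, _EPS, 1 - _EPS)


def combine_pvalues(p, method: str = "fisher") -> tuple[float, float]:
    """Combine independent p-values.

    Fisher: ``X2 = -2 * sum(log p)`` against chi-square with 2k df.
    Stouffer: ``Z = sum(Phi^-1(1 - p)) / sqrt(k)`` against the upper
    normal tail.  Returns ``(statistic, combined_p)``.
    """
    p = _clip_p(np.asarray(p, dtype=float))
    k = len(p)
    if k == 0:
        raise EnrichmentError("no p-values to combine")
    if method == "fisher":
        x2 = -2 * np.sum(np.log(p))
        return float(x2), float(sps.chi2.sf(x2, 2 * k))
    if method == "stouffer":
        z = np.sum(sps.norm.isf(p)) / np.sqrt(k)
        return float(z), float(sps.norm.sf(z))
    raise EnrichmentError(f"unknown combination method {method!r}")


# ---------------------------------------------------------------------------
# functional class scoring


def _set_statistic(method, pvals, stats_vals):
    if method == "fisher":
        return combine_pvalues(pvals, "fisher")[0]
    if method in ("stouffer", "reporter"):
        return float(np.sum(sps.norm.isf(_clip_p(pvals))) / np.sqrt(len(pvals)))
    if method == "median":
        return float(np.median(stats_vals))
    if method == "mean":
        return float(np.mean(stats_vals))
    raise EnrichmentError(f"unknown FCS method {method!r}")


def fcs_enrich(
    stats_table: pd.DataFrame,
    sets: list[AnnotationSet],
    method: str = "reporter",
    n_perm: int = 1000,
    seed: int | None = None,
    n_background: int = 1000,
) -> pd.DataFrame:
    """Functional class scoring over annotation sets.

    ``stats_table`` needs columns ``entity_id``, ``p`` and (for
    median/mean) ``statistic``.  The set statistic is evaluated against
    an entity-label permutation null: random same-size draws from the
    whole universe, ``p = (1 + #{perm >= obs}) / (n_perm + 1)``, BH-
    adjusted across terms.  The reporter method first standardizes the
    Stouffer Z by the mean and standard deviation of Z over
    ``n_background`` random same-size sets.  The test is one-sided: large
    set statistics are significant; for median/mean the side relative to
    the permutation centre is reported as ``direction``.
    """
    if n_perm < 100:
        raise EnrichmentError("n_perm must be >= 100")
    if method not in FCS_METHODS:
        raise EnrichmentError(f"unknown FCS method {method!r}")
    universe = stats_table["entity_id"].astype(str).to_numpy()
    pv = stats_table["p"].to_numpy(dtype=float)
    sv = (
        stats_table["statistic"].to_numpy(dtype=float)
        if "statistic" in stats_table.columns
        else sps.norm.isf(_clip_p(pv))
    )
    index = {e: i for i, e in enumerate(universe)}
    rng = np.random.default_rng(seed)
    n_univ = len(universe)

    # background moments per distinct set size (reporter only)
    sizes = set()
    usable = []
    for s in sets:
        members = [index[m] for m in s.members if m in index]
        if not members:
            warnings.warn(f"set {s.term_id!r} has no members in the universe; dropped")
            continue
        usable.append((s, np.array(members)))
        sizes.add(len(members))
    bg: dict[int, tuple[float, float]] = {}
    if method == "reporter":
        for k in sorted(sizes):
            draws = np.empty(n_background)
            for b in range(n_background):
                pick = rng.choice(n_univ, size=k, replace=False)
                draws[b] = _set_statistic("stouffer", pv[pick], sv[pick])
            bg[k] = (float(draws.mean()), float(draws.std(ddof=1)) or 1.0)

    def observed(members):
        stat = _set_statistic(method, pv[members], sv[members])
        if method == "reporter":
            mu, sd = bg[len(members)]
            stat = (stat - mu) / sd
        return stat

    rows = []
    for s, members in usable:
        k = len(members)
        obs = observed(members)
        perm = np.empty(n_perm)
        for b in range(n_perm):
            pick = rng.choice(n_univ, size=k, replace=False)
            perm[b] = observed(pick)
        p = (1 + np.sum(perm >= obs)) / (n_perm + 1)
        direction = ""
        if method in ("median", "mean"):
            direction = "up" if obs >= float(np.median(perm)) else "down"
        rows.append(
            {
                "term_id": s.term_id,
                "term_name": s.term_name,
                "size": k,
                "method": method,
                "statistic": obs,
                "p": float(p),
                "direction": direction,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["pFDR"] = adjust_bh(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# overrepresentation analysis


def ora_hypergeometric(
    selected, universe, sets: list[AnnotationSet]
) -> pd.DataFrame:
    """Hypergeometric overrepresentation test per annotation term.

    With N universe entities, K of them annotated to the term, and n
    selected entities of which k are annotated, the p-value is
    ``P(X >= k)`` for X ~ Hypergeometric(N, K, n).  BH adjustment across
    terms.
    """
    selected = set(map(str, selected))
    universe = set(map(str, universe))
    stray = selected - universe
    if stray:
        raise EnrichmentError(f"selected ids outside the universe: {sorted(stray)}")
    n_univ, n_sel = len(universe), len(selected)
    rows = []
    for s in sets:
        annotated = s.members & universe
        if not annotated:
            continue
        k_ann = len(annotated)
        overlap = len(annotated & selected)
        p = float(sps.hypergeom.sf(overlap - 1, n_univ, k_ann, n_sel))
        rows.append(
            {
                "term_id": s.term_id,
                "term_name": s.term_name,
                "size": k_ann,
                "overlap": overlap,
                "method": "hypergeometric",
                "p": min(1.0, p),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["pFDR"] = adjust_bh(out["p"].to_numpy())
    return out


def multitype_ora(
    selected_by_type: dict, universe_by_type: dict, sets: list[AnnotationSet]
) -> pd.DataFrame:
    """ORA per node type, Fisher-combined per term across node types.

    Used on heterogeneous networks mixing e.g. genes and compounds: each
    type is tested against its own universe, and a term annotated in
    several types gets the Fisher combination of its per-type p-values.
    """
    if not selected_by_type:
        raise EnrichmentError("need at least one node type")
    per_type = {}
    for t, sel in selected_by_type.items():
        res = ora_hypergeometric(sel, universe_by_type[t], sets)
        if len(res):
            per_type[t] = res.set_index("term_id")
    terms: dict[str, dict] = {}
    for t, res in per_type.items():
        for term_id, r in res.iterrows():
            entry = terms.setdefault(
                term_id,
                {"term_id": term_id, "term_name": r["term_name"], "size": 0,
                 "overlap": 0, "p_by_type": {}},
            )
            entry["size"] += int(r["size"])
            entry["overlap"] += int(r["overlap"])
            entry["p_by_type"][t] = float(r["p"])
    rows = []
    for entry in terms.values():
        ps = list(entry["p_by_type"].values())
        if len(ps) == 1:
            comb = ps[0]
        else:
            comb = combine_pvalues(ps, "fisher")[1]
        rows.append(
            {
                "term_id": entry["term_id"],
                "term_name": entry["term_name"],
                "size": entry["size"],
                "overlap": entry["overlap"],
                "method": "hypergeometric+fisher",
                "n_types": len(ps),
                "p": comb,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("term_id").reset_index(drop=True)
        out["pFDR"] = adjust_bh(out["p"].to_numpy())
    return out


def term_frequencies(terms) -> pd.DataFrame:
    """Multiset counts of annotation terms (the WordCloud numbers).

    Sorted by count descending, ties broken lexicographically.
    """
    counts: dict[str, int] = {}
    for t in terms:
        counts[str(t)] = counts.get(str(t), 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["term", "count"])
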