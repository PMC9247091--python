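"""Gene-set enrichment on a ranked gene list.

Implements the weighted Kolmogorov-Smirnov running-sum enrichment score with
a gene-label permutation null, normalized enrichment scores, and the
tail-ratio FDR q-value.  Gene-label (not sample-label) permutation is used
because a four-donor-per-arm design has far too few sample permutations to
build a null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, ordered deduplicated members)."""

    sets: dict = field(default_factory=dict)  # name -> (description, [members])

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def add(self, name: str, description: str, members: list[str]) -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        dedup = list(dict.fromkeys(members))
        if not dedup:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = (description, dedup)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]


def read_gmt(path: str) -> GeneSetCollection:
    """Parse a GMT file: one set per line, name TAB description TAB genes...

    Duplicate members within a line are collapsed; lines with fewer than
    three fields raise with the offending line number.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        n_lines = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            coll.add(fields[0], fields[1], fields[2:])
    if n_lines == 0:
        warnings.warn(f"GMT file {path} contains no gene sets")
    return coll


def write_gmt(coll: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in coll:
            fh.write("\t".join([name, desc, *members]) + "\n")


def rank_genes(de: pd.DataFrame, metric: str = "wald_stat") -> pd.Series:
    """Ranked gene list: descending signed metric, gene id breaking ties.

    Metrics: "wald_stat" (signed Wald statistic, the default), "log2fc",
    "signed_logp" (-log10(p) carrying the fold-change sign).  Genes with NaN
    metric are excluded with a warning.
    """
    if metric == "wald_stat":
        values = de["stat"]
    elif metric == "log2fc":
        values = de["log2fc"]
    elif metric == "signed_logp":
        with np.errstate(divide="ignore"):
            values = -np.log10(de["pvalue"].clip(lower=1e-300)) * np.sign(de["log2fc"])
        values = pd.Series(values, index=de.index)
    else:
        raise KeyError(f"unknown ranking metric {metric!r}")
    s = pd.Series(values.to_numpy(), index=de["gene_id"].to_numpy())
    nan = s.isna()
    if nan.any():
        warnings.warn(f"{int(nan.sum())} gene(s) with NaN metric excluded from ranking")
        s = s[~nan]
    order = sorted(range(len(s)), key=lambda i: (-s.iloc[i], s.index[i]))
    return s.iloc[order]


def _es_candidates(
    positions: np.ndarray, weights: np.ndarray, n_universe: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Running-sum values just after and just before each hit.

    ``positions``: (n_rows, k) sorted 0-based hit indices; ``weights``: the
    per-gene |score|^p vector over the whole universe.  The running sum is
    piecewise linear between hits, so its extrema occur at these 2k points.
    """
    n_rows, k = positions.shape
    wh = weights[positions]
    sums = wh.sum(axis=1, keepdims=True)
    # a set whose hit scores are all zero gets equal hit weights
    zero = sums[:, 0] == 0
    if zero.any():
        wh = wh.copy()
        wh[zero] = 1.0
        sums = wh.sum(axis=1, keepdims=True)
    cum = np.cumsum(wh, axis=1) / sums
    miss_pen = 0.0 if n_universe == k else 1.0 / (n_universe - k)
    idx = np.arange(1, k + 1)
    after = cum - (positions + 1 - idx[None, :]) * miss_pen
    before = np.concatenate([np.zeros((n_rows, 1)), cum[:, :-1]], axis=1) - (
        positions - (idx[None, :] - 1)
    ) * miss_pen
    return after, before, cum


def _pick_es(after: np.ndarray, before: np.ndarray) -> np.ndarray:
    """Signed extremum of the running sum; a |max| = |min| tie goes positive.

    The maximum of the running sum is always attained just after a hit and
    the minimum just before one (or at the terminal zero), so the 2k
    candidate points suffice.
    """
    maxv = after.max(axis=1)
    minv = np.minimum(before.min(axis=1), 0.0)
    # 1e-12 guard so summation-order noise cannot flip a genuine tie
    return np.where(maxv >= -minv - 1e-12, maxv, minv)


def enrichment_score(
    ranked: pd.Series, gene_set: list[str], weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted running-sum enrichment score of one set on a ranked list.

    A hit at rank i increments the running sum by |score_i|^weight over the
    summed hit weights; a miss decrements by 1/(N - N_hits).  ES is the
    extremum (sign retained).  The leading edge is the members at or before
    a positive extremum, or at or after a negative one.

    Returns (ES, full running-sum array of length N, leading-edge genes).
    """
    genes = ranked.index.to_numpy()
    n = len(genes)
    members = set(gene_set)
    hit = np.isin(genes, list(members))
    k = int(hit.sum())
    if k == 0:
        raise ValueError("gene set has no members in the ranked universe")
    w = np.abs(ranked.to_numpy()) ** weight
    positions = np.flatnonzero(hit)[None, :]
    after, before, cum = _es_candidates(positions, w, n)
    es = float(_pick_es(after, before)[0])

    inc = np.zeros(n)
    wh = w[positions[0]]
    wh_sum = wh.sum() if wh.sum() > 0 else float(k)
    inc[hit] = (wh if wh.sum() > 0 else 1.0) / wh_sum
    if n > k:
        inc[~hit] = -1.0 / (n - k)
    running = np.cumsum(inc)

    if es >= 0:
        cut = positions[0][int(np.argmax(after[0]))]
        leading = [g for g in genes[: cut + 1] if g in members]
    else:
        cut = positions[0][int(np.argmin(before[0]))]
        leading = [g for g in genes[cut:] if g in members]
    return es, running, leading


def _null_es(
    rng: np.random.Generator,
    weights: np.ndarray,
    n_universe: int,
    set_size: int,
    n_perm: int,
) -> np.ndarray:
    """Null ES from uniformly re-drawn member positions (gene-label permutation)."""
    es = np.empty(n_perm)
    chunk = max(1, int(2e6 // max(set_size, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        u = rng.random((b, n_universe))
        positions = np.sort(np.argpartition(u, set_size - 1, axis=1)[:, :set_size], axis=1)
        after, before, _ = _es_candidates(positions, weights, n_universe)
        es[done : done + b] = _pick_es(after, before)
        done += b
    return es


def permutation_test(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 10,
    max_size: int = 500,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Permutation enrichment over a collection: ES, NES, p, FDR q.

    The null reassigns set membership uniformly at random over the ranked
    universe (same set size).  NES = ES / mean(|null ES| of the same sign);
    p = (1 + #{same-sign null at least as extreme}) / (1 + #same-sign null).
    q is the standard tail-ratio FDR over pooled null and observed NES,
    falling back to BH on the permutation p whenever a sign stratum holds
    fewer than 50 null values.
    """
    if n_perm < 50:
        raise ValueError("n_perm < 50 gives unstable q-values")
    rng = np.random.default_rng(seed)
    genes = ranked.index.to_numpy()
    universe = set(genes)
    n = len(genes)
    w = np.abs(ranked.to_numpy()) ** weight

    rows = []
    null_nes_all: list[np.ndarray] = []
    skipped = []
    for name, (_desc, members) in collection:
        present = [g for g in members if g in universe]
        size = len(present)
        if size == 0:
            skipped.append(name)
            continue
        if size < min_size or size > max_size:
            continue
        es, _running, leading = enrichment_score(ranked, present, weight)
        null = _null_es(rng, w, n, size, n_perm)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        mean_abs = np.abs(same).mean() if len(same) else np.nan
        nes = es / mean_abs if mean_abs and mean_abs > 0 else np.nan
        p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + len(same))
        # null NES: normalize each null ES by its own sign stratum's mean
        pos, neg = null[null > 0], null[null < 0]
        nn = np.concatenate(
            [
                pos / pos.mean() if len(pos) else pos,
                neg / np.abs(neg).mean() if len(neg) else neg,
            ]
        )
        null_nes_all.append(nn)
        rows.append(
            {
                "set": name,
                "size": size,
                "es": es,
                "nes": nes,
                "pvalue": p,
                "leading_edge": ",".join(leading),
                "direction": int(np.sign(es)),
            }
        )
    if skipped:
        warnings.warn(f"sets with no member in the universe skipped: {skipped}")
    result = pd.DataFrame(rows)
    if result.empty:
        result["fdr_q"] = []
        return result

    null_nes = np.concatenate(null_nes_all) if null_nes_all else np.array([])
    obs_nes = result["nes"].to_numpy()
    q = np.full(len(result), np.nan)
    from .decore import bh_adjust

    bh_q = bh_adjust(result["pvalue"].to_numpy())
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes):
            q[i] = bh_q[i]
            continue
        if nes >= 0:
            null_str = null_nes[null_nes >= 0]
            obs_str = obs_nes[obs_nes >= 0]
            if len(null_str) < 50:
                q[i] = bh_q[i]
                continue
            num = (null_str >= nes).mean()
            den = (obs_str >= nes).mean()
        else:
            null_str = null_nes[null_nes <= 0]
            obs_str = obs_nes[obs_nes <= 0]
            if len(null_str) < 50:
                q[i] = bh_q[i]
                continue
            num = (null_str <= nes).mean()
            den = (obs_str <= nes).mean()
        q[i] = min(num / den, 1.0) if den > 0 else 1.0
    result["fdr_q"] = q
    return result[
        ["set", "size", "es", "nes", "pvalue", "fdr_q", "leading_edge", "direction"]
    ]


def top_pathways(result: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """The n most regulated sets: q ascending, |NES| descending, name tiebreak."""
    if result.empty:
        raise ValueError("empty enrichment result")
    ranked = result.assign(_abs=lambda d: d["nes"].abs()).sort_values(
        ["fdr_q", "_abs", "set"], ascending=[True, False, True], kind="mergesort"
    )
    return ranked.drop(columns="_abs").head(n).reset_index(drop=True)
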