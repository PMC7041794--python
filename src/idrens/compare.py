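"""Mutant-vs-wild-type ensemble comparison metrics.

Three complementary views:

* local: absolute deviation of the mean CA pairwise-distance maps,
* global: Hellinger distance between the 2D (Rg, asphericity) histograms,
* heterogeneity: average structural dissimilarity over sampled conformation
  pairs within one ensemble.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from idrens.descriptors import DescriptorTable, instantaneous_distance_maps
from idrens.sampler import Ensemble

DEFAULT_BINS = 30
DEFAULT_N_PAIRS = 10_000

#: Minimum |i - j| sequence separation for distance-based metrics; bonded
#: pairs are geometric constants and would dilute the signal.
MIN_SEPARATION = 2


def local_difference(mut: DescriptorTable, wt: DescriptorTable
                     ) -> tuple[np.ndarray, float]:
    """(deviation map, scalar) for the mean pairwise-distance maps.

    map_ij = |<d_ij>_mut - <d_ij>_wt|; the scalar is the unweighted mean over
    pairs with |i - j| >= 2.  Symmetric in its arguments.
    """
    if mut.n_res != wt.n_res:
        raise ValueError("descriptor tables have different sequence lengths")
    dev = np.abs(mut.mean_map - wt.mean_map)
    i, j = np.triu_indices(mut.n_res, k=MIN_SEPARATION)
    return dev, float(dev[i, j].mean())


def hellinger_from_counts(p_counts: np.ndarray, q_counts: np.ndarray) -> float:
    """Hellinger distance between two (unnormalized) histograms."""
    p = np.asarray(p_counts, dtype=float).ravel()
    q = np.asarray(q_counts, dtype=float).ravel()
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sqrt(0.5 * ((np.sqrt(p) - np.sqrt(q)) ** 2).sum()))


def global_difference(mut: DescriptorTable, wt: DescriptorTable,
                      bins: int = DEFAULT_BINS) -> float:
    """Hellinger distance between the normalized 2D (Rg, asphericity)
    histograms of two ensembles on a shared grid spanning the pooled range.

    Bounded in [0, 1]; 0 for identical tables, 1 for disjoint supports.
    """
    for table in (mut, wt):
        if len(table) == 0:
            raise ValueError("empty descriptor table")
    rg_m = mut.per_conformation["rg"].to_numpy()
    rg_w = wt.per_conformation["rg"].to_numpy()
    d_m = mut.per_conformation["asphericity"].to_numpy()
    d_w = wt.per_conformation["asphericity"].to_numpy()
    rg_edges = np.linspace(min(rg_m.min(), rg_w.min()),
                           max(rg_m.max(), rg_w.max()), bins + 1)
    d_edges = np.linspace(min(d_m.min(), d_w.min()),
                          max(d_m.max(), d_w.max()), bins + 1)
    # guard against zero-width ranges (degenerate but legal inputs)
    if rg_edges[0] == rg_edges[-1]:
        rg_edges = np.linspace(rg_edges[0] - 0.5, rg_edges[0] + 0.5, bins + 1)
    if d_edges[0] == d_edges[-1]:
        d_edges = np.linspace(d_edges[0] - 0.5, d_edges[0] + 0.5, bins + 1)
    h_m, _, _ = np.histogram2d(rg_m, d_m, bins=(rg_edges, d_edges))
    h_w, _, _ = np.histogram2d(rg_w, d_w, bins=(rg_edges, d_edges))
    return hellinger_from_counts(h_m, h_w)


def heterogeneity(ens: Ensemble, n_pairs: int = DEFAULT_N_PAIRS,
                  seed: int = 0) -> float:
    """Mean structural dissimilarity D in [0, 1] over sampled conformation
    pairs.

    For a pair (m, n) the similarity is the Pearson correlation of the
    upper-triangle (|i - j| >= 2) entries of their instantaneous CA distance
    maps, mapped to [0, 1] via (s + 1) / 2; D is the mean of one minus that.
    """
    n_conf = len(ens)
    if n_conf < 2:
        raise ValueError("heterogeneity requires at least 2 conformations")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    m = rng.integers(0, n_conf, size=n_pairs)
    n = rng.integers(0, n_conf - 1, size=n_pairs)
    n[n >= m] += 1  # distinct partner, uniform over the off-diagonal
    maps = instantaneous_distance_maps(ens)
    i, j = np.triu_indices(ens.n_res, k=MIN_SEPARATION)
    vecs = maps[:, i, j]
    return float(np.mean([1.0 - (pearson(vecs[a], vecs[b]) + 1.0) / 2.0
                          for a, b in zip(m, n)]))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; 1.0 for two zero-variance identical vectors."""
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0.0 and ny == 0.0:
        return 1.0
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


@dataclass
class ComparisonResult:
    """All comparison metrics for one variant against the wild type."""

    variant: str
    local_map: np.ndarray
    local_deviation: float
    global_distance: float
    heterogeneity: float

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "local_deviation_A": self.local_deviation,
            "global_distance": self.global_distance,
            "heterogeneity": self.heterogeneity,
        }


def compare_to_wildtype(variant_table: DescriptorTable, wt_table: DescriptorTable,
                        variant_ens: Ensemble, *, bins: int = DEFAULT_BINS,
                        n_pairs: int = DEFAULT_N_PAIRS, seed: int = 0
                        ) -> ComparisonResult:
    dev_map, dev = local_difference(variant_table, wt_table)
    return ComparisonResult(
        variant=variant_table.name,
        local_map=dev_map,
        local_deviation=dev,
        global_distance=global_difference(variant_table, wt_table, bins=bins),
        heterogeneity=heterogeneity(variant_ens, n_pairs=n_pairs, seed=seed),
    )


def rank_variants(results: list[ComparisonResult],
                  binding_labels: dict[str, str]) -> pd.DataFrame:
    """Cross-variant report: metric values, per-metric ranks, and a
    rank-association statistic (point-biserial via Spearman) between each
    metric and the binary binding label ('impaired' / 'unimpaired').

    The association is reported, not tested; a constant metric yields a
    flagged NaN association.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 variants to rank")
    missing = [r.variant for r in results if r.variant not in binding_labels]
    if missing:
        raise ValueError(f"missing binding labels for: {', '.join(missing)}")
    bad = {v for v in binding_labels.values()} - {"impaired", "unimpaired"}
    if bad:
        raise ValueError(f"labels must be 'impaired'/'unimpaired', got {sorted(bad)}")

    df = pd.DataFrame([r.to_dict() for r in results]).set_index("variant")
    df["binding"] = [binding_labels[v] for v in df.index]
    impaired = (df["binding"] == "impaired").astype(float)
    metrics = ["local_deviation_A", "global_distance", "heterogeneity"]
    assoc = {}
    for m in metrics:
        df[f"rank_{m}"] = df[m].rank(ascending=False).astype(int)
        if df[m].nunique() < 2 or impaired.nunique() < 2:
            assoc[m] = float("nan")  # undefined association, flagged as NaN
        else:
            assoc[m] = float(stats.spearmanr(df[m], impaired).statistic)
    df.attrs["association_with_impairment"] = assoc
    return df


def write_report(results: list[ComparisonResult], directory: str | Path,
                 binding_labels: dict[str, str] | None = None) -> list[Path]:
    """Serialize comparison results to CSV + JSON (maps as CSV matrices)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = pd.DataFrame([r.to_dict() for r in results])
    paths = [directory / "comparison.csv"]
    rows.to_csv(paths[0], index=False)
    payload = {"variants": [r.to_dict() for r in results]}
    if binding_labels is not None:
        ranked = rank_variants(results, binding_labels)
        payload["association_with_impairment"] = ranked.attrs[
            "association_with_impairment"]
    p = directory / "comparison.json"
    p.write_text(json.dumps(payload, indent=2))
    paths.append(p)
    for r in results:
        p = directory / f"{r.variant}_local_deviation.csv"
        pd.DataFrame(r.local_map).to_csv(p, index=False)
        paths.append(p)
    return paths
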