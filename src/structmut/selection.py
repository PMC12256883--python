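"""Signature-conditioned selection inference on protein structures.

Three tests live here:

* A Monte-Carlo selection test: the null model is the signature-weighted
  universe of every possible missense change of a gene; sets of the observed
  size are drawn with replacement by weight and a structural metric (distance
  to hinge residues, ddG, SASA, ...) is averaged per draw.  The observed mean
  is compared to this permutation distribution with the add-one rule
  p = (b + 1) / (n_perm + 1).
* A per-gene dN/dS estimate with expected nonsynonymous/synonymous
  proportions taken from the same signature-weighted enumeration, and a
  1-df Poisson likelihood-ratio test of omega = 1.
* Nonrandom mutational clustering (NMC): for every pair of order statistics
  x(i) < x(j) of the n mutation positions, the fractional span
  (x(j) - x(i)) / L is referred to Beta(j - i, n - (j - i) + 1); pairs
  significant after Bonferroni correction over all n(n-1)/2 pairs are merged
  into maximal clusters.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import CodingGene, MutationRecord, MutationalSignature, enumerate_snvs


class CoverageError(KeyError):
    """A metric or universe lookup is missing required keys."""

    def __init__(self, missing, what="metric"):
        self.missing = list(missing)
        shown = ", ".join(map(str, self.missing[:10]))
        more = "" if len(self.missing) <= 10 else f" (+{len(self.missing) - 10} more)"
        super().__init__(f"{what} not defined for: {shown}{more}")


@dataclass
class MutationUniverse:
    """Every possible missense single-nucleotide change of one gene.

    ``entries`` has one row per CDS change with columns cds_position,
    ref_base, alt_base, protein_position, ref_aa, alt_aa, channel, weight;
    weights are signature probabilities renormalized to sum to 1.
    """

    gene: str
    entries: pd.DataFrame

    def __post_init__(self):
        w = self.entries["weight"].to_numpy()
        if (w < 0).any():
            raise ValueError("negative universe weight")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("universe weights must sum to 1")

    def aa_level(self) -> pd.DataFrame:
        """Aggregate to (protein_position, ref_aa, alt_aa) summing weights."""
        return (
            self.entries.groupby(
                ["protein_position", "ref_aa", "alt_aa"], as_index=False
            )["weight"]
            .sum()
            .sort_values(["protein_position", "ref_aa", "alt_aa"], ignore_index=True)
        )


def build_universe(gene: CodingGene, signature: MutationalSignature) -> MutationUniverse:
    """Enumerate all missense changes of a gene, weighted by the signature."""
    snvs = enumerate_snvs(gene)
    mis = snvs[snvs["consequence"] == "missense"].copy()
    if mis.empty:
        raise ValueError(f"{gene.gene}: no possible missense change")
    mis["weight"] = signature.channel_probs[mis["channel"].to_numpy()]
    total = mis["weight"].sum()
    if total <= 0:
        raise ValueError(
            f"{gene.gene}: signature assigns zero mass to every missense change"
        )
    mis["weight"] /= total
    return MutationUniverse(gene=gene.gene, entries=mis.reset_index(drop=True))


MetricFunction = Callable[[int, str, str], float]


def metric_from_table(table: pd.DataFrame | str | Path) -> MetricFunction:
    """Wrap a (position, ref_aa, alt_aa, value) TSV/DataFrame as a metric."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    lookup = {
        (int(p), r, a): float(v)
        for p, r, a, v in zip(
            table["position"], table["ref_aa"], table["alt_aa"], table["value"]
        )
    }

    def metric(pos: int, ref_aa: str, alt_aa: str) -> float:
        try:
            return lookup[(pos, ref_aa, alt_aa)]
        except KeyError:
            raise CoverageError([(pos, ref_aa, alt_aa)]) from None

    return metric


def metric_from_positions(values: Mapping[int, float] | np.ndarray) -> MetricFunction:
    """Metric depending on protein position only (e.g. distance to hinges).

    Accepts a mapping position -> value or an array indexed by position - 1.
    """
    if isinstance(values, np.ndarray):
        arr = values

        def metric(pos, ref_aa, alt_aa):
            if not 1 <= pos <= arr.size:
                raise CoverageError([(pos, ref_aa, alt_aa)])
            return float(arr[pos - 1])

    else:
        mapping = dict(values)

        def metric(pos, ref_aa, alt_aa):
            try:
                return float(mapping[pos])
            except KeyError:
                raise CoverageError([(pos, ref_aa, alt_aa)]) from None

    return metric


def read_foldx_dif(path: str | Path, protein_sequence: str) -> pd.DataFrame:
    """Parse a FoldX "Dif_*" saturation table into the metric interchange format.

    The Dif dialect is a TSV whose first column is the mutation tag
    (e.g. ``VA310M`` = ref V, chain A, position 310, alt M) and whose
    ``total energy`` column is the ddG in kcal/mol.  Returns columns
    position, ref_aa, alt_aa, value.
    """
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    energy_col = next(
        (c for c in df.columns if c.strip().lower() in ("total energy", "total_energy")),
        df.columns[1],
    )
    rows = []
    import re

    for tag, val in zip(df[first], df[energy_col]):
        m = re.fullmatch(r"([A-Z])([A-Za-z0-9])(\d+)([A-Z])", str(tag).strip().rstrip(";"))
        if not m:
            continue
        ref, _chain, pos, alt = m.group(1), m.group(2), int(m.group(3)), m.group(4)
        if 1 <= pos <= len(protein_sequence) and protein_sequence[pos - 1] != ref:
            raise ValueError(f"FoldX tag {tag}: sequence has {protein_sequence[pos - 1]}")
        rows.append({"position": pos, "ref_aa": ref, "alt_aa": alt, "value": float(val)})
    return pd.DataFrame(rows)


@dataclass
class SelectionTestResult:
    observed_mean: float
    expected_mean: float
    effect_size: float  # observed - expected
    p_value: float
    n_permutations: int
    n_observed: int
    seed: int | None
    tail: str
    statistic: str = "mean"


def _resolve_metric(
    metric: MetricFunction | Mapping, keys: Iterable[tuple[int, str, str]]
) -> np.ndarray:
    keys = list(keys)
    if isinstance(metric, Mapping):
        missing = [k for k in keys if k not in metric]
        if missing:
            raise CoverageError(missing)
        return np.array([float(metric[k]) for k in keys])
    vals = np.empty(len(keys))
    for i, (pos, ref, alt) in enumerate(keys):
        vals[i] = metric(pos, ref, alt)
    return vals


def monte_carlo_selection_test(
    observed: Sequence,
    universe: MutationUniverse,
    metric: MetricFunction | Mapping,
    n_permutations: int = 100_000,
    seed: int | None = None,
    tail: str = "two_sided",
    statistic: str = "mean",
) -> SelectionTestResult:
    """Compare observed mutations' metric values to the signature null.

    ``observed`` is a sequence of ``(protein_position, ref_aa, alt_aa)``
    triples or MutationRecords with a parseable protein change.  Sets of the
    observed size are drawn with replacement from the weighted universe; the
    permutation statistic is the mean (or median) metric of the drawn set.
    p-values use the add-one rule and are deterministic given ``seed``.
    """
    if tail not in ("two_sided", "lower", "upper"):
        raise ValueError("tail must be two_sided, lower or upper")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be mean or median")
    obs_keys = []
    for o in observed:
        if isinstance(o, MutationRecord):
            obs_keys.append(o.aa_key())
        else:
            pos, ref, alt = o
            obs_keys.append((int(pos), ref, alt))
    if not obs_keys:
        raise ValueError("need at least one observed mutation")

    aa = universe.aa_level()
    uni_keys = list(
        zip(aa["protein_position"].astype(int), aa["ref_aa"], aa["alt_aa"])
    )
    key_set = set(uni_keys)
    absent = [k for k in obs_keys if k not in key_set]
    if absent:
        raise CoverageError(absent, what="universe")

    metric_vals = _resolve_metric(metric, uni_keys)
    weights = aa["weight"].to_numpy()
    stat_fn = np.mean if statistic == "mean" else np.median

    obs_vals = _resolve_metric(metric, obs_keys)
    observed_stat = float(stat_fn(obs_vals))
    expected_mean = float(np.sum(weights * metric_vals))

    rng = np.random.default_rng(seed)
    n_obs = len(obs_keys)
    lower_count = 0
    upper_count = 0
    chunk = max(1, int(2e6) // n_obs)
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        draws = rng.choice(metric_vals, size=(m, n_obs), replace=True, p=weights)
        perm = stat_fn(draws, axis=1)
        lower_count += int(np.sum(perm <= observed_stat))
        upper_count += int(np.sum(perm >= observed_stat))
        done += m

    p_lower = (lower_count + 1) / (n_permutations + 1)
    p_upper = (upper_count + 1) / (n_permutations + 1)
    if tail == "lower":
        p = p_lower
    elif tail == "upper":
        p = p_upper
    else:
        p = min(1.0, 2.0 * min(p_lower, p_upper))
    return SelectionTestResult(
        observed_mean=observed_stat,
        expected_mean=expected_mean,
        effect_size=observed_stat - expected_mean,
        p_value=p,
        n_permutations=n_permutations,
        n_observed=n_obs,
        seed=seed,
        tail=tail,
        statistic=statistic,
    )


@dataclass
class DnDsResult:
    gene: str
    obs_N: int
    obs_S: int
    exp_N: float
    exp_S: float
    ratio: float
    log2_ratio: float
    p_value: float
    fallback: bool = False  # 0.5 added to all four counts (obs_S or obs_N was 0)


def dnds_estimate(
    records: Iterable[MutationRecord],
    gene: CodingGene,
    signature: MutationalSignature,
) -> DnDsResult:
    """Signature-aware dN/dS for one gene with a Poisson likelihood-ratio test.

    Model: obs_N ~ Poisson(mu * rN * omega), obs_S ~ Poisson(mu * rS) where
    rN, rS are the signature-expected nonsynonymous/synonymous proportions of
    the gene's possible changes (nonsense counts as nonsynonymous).  mu is
    profiled out; the LRT of omega = 1 has 1 df.
    """
    snvs = enumerate_snvs(gene)
    w = signature.channel_probs[snvs["channel"].to_numpy()]
    conseq = snvs["consequence"].to_numpy()
    rN = float(w[(conseq == "missense") | (conseq == "nonsense")].sum())
    rS = float(w[conseq == "synonymous"].sum())
    if rN <= 0 or rS <= 0:
        raise ValueError(f"{gene.gene}: degenerate expected proportions")

    obs_N = obs_S = 0
    for rec in records:
        if rec.consequence in ("missense", "nonsense"):
            obs_N += 1
        elif rec.consequence == "synonymous":
            obs_S += 1
    total = obs_N + obs_S
    if total == 0:
        raise ValueError(f"{gene.gene}: no observed substitutions")

    exp_N = total * rN / (rN + rS)
    exp_S = total * rS / (rN + rS)

    fallback = obs_S == 0 or obs_N == 0
    if fallback:
        ratio = ((obs_N + 0.5) / (exp_N + 0.5)) / ((obs_S + 0.5) / (exp_S + 0.5))
    else:
        ratio = (obs_N / exp_N) / (obs_S / exp_S)

    # LRT: saturated alternative fits both counts exactly; null shares mu.
    def _xlogy(x, y):
        return 0.0 if x == 0 else x * np.log(x / y)

    lrt = 2.0 * (_xlogy(obs_N, exp_N) + _xlogy(obs_S, exp_S))
    p = float(stats.chi2.sf(lrt, df=1))
    return DnDsResult(
        gene=gene.gene,
        obs_N=obs_N,
        obs_S=obs_S,
        exp_N=exp_N,
        exp_S=exp_S,
        ratio=float(ratio),
        log2_ratio=float(np.log2(ratio)) if ratio > 0 else float("-inf"),
        p_value=p,
        fallback=fallback,
    )


@dataclass
class ClusterCall:
    start_residue: int
    end_residue: int
    corrected_p: float


def nmc_clusters(
    positions: Sequence[int], protein_length: int, alpha: float = 0.05
) -> list[ClusterCall]:
    """Nonrandom mutational clustering over 1D residue positions.

    Under a uniform null the fractional span between order statistics i < j
    of n positions follows Beta(j - i, n - (j - i) + 1).  All n(n-1)/2 pairs
    are tested (recurrent positions count as separate order statistics),
    Bonferroni-corrected, and significant pairs merged into maximal
    overlapping clusters.
    """
    positions = np.asarray(sorted(positions), dtype=float)
    n = positions.size
    if n < 2:
        return []
    if positions.min() < 1 or positions.max() > protein_length:
        raise ValueError("positions must lie within [1, protein_length]")
    i_idx, j_idx = np.triu_indices(n, k=1)
    k = j_idx - i_idx
    # +1 continuity correction: integer positions cover unit intervals, so
    # coincident/adjacent residues do not yield a spuriously zero span
    span = (positions[j_idx] - positions[i_idx] + 1) / (protein_length + 1)
    pvals = stats.beta.cdf(span, k, n - k + 1)
    m = n * (n - 1) / 2
    corrected = np.minimum(pvals * m, 1.0)
    sig = corrected <= alpha
    if not sig.any():
        return []
    intervals = sorted(
        zip(positions[i_idx[sig]], positions[j_idx[sig]], corrected[sig])
    )
    calls: list[ClusterCall] = []
    cur_s, cur_e, cur_p = intervals[0]
    for s, e, p in intervals[1:]:
        if s <= cur_e:  # overlapping or touching -> merge
            cur_e = max(cur_e, e)
            cur_p = min(cur_p, p)
        else:
            calls.append(ClusterCall(int(cur_s), int(cur_e), float(cur_p)))
            cur_s, cur_e, cur_p = s, e, p
    calls.append(ClusterCall(int(cur_s), int(cur_e), float(cur_p)))
    return calls
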