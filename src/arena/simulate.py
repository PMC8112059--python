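"""Synthetic generators for every pipeline input.

All generators draw from streams derived deterministically from
``SimulationConfig.seed``, so each stage is reproducible in isolation:
regenerating the occupancy table does not depend on whether the loop list
was generated first.

Planted structure
-----------------
* regions: non-overlapping intervals on a synthetic contig, with design
  groups (clinical / ARE-only / positive-control) and, for clinical
  regions, enhancer classes at the configured proportions;
* STARR-seq counts: negative-binomial with class-dependent RNA/plasmid and
  DHT/EtOH mean ratios and log-normal library sizes;
* occupancy: a designated subset of factors shifts its score distribution
  at inducible regions; matched control scores come from the null;
* loops: inducible regions initiate ``hub_enrichment`` times more loops
  and preferentially contact up-regulated-gene TSSs; partner regions are
  chosen proportionally to their own rate so the realised mean degree
  ratio equals the planted multiplier;
* co-accessibility: pair scores shared between conditions except at pairs
  adjacent to an inducible region, whose DHT score gains
  ``coaccess_gain``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from arena.config import CHROM, CLASSES, SimulationConfig

_STREAMS = {"regions": 0, "counts": 1, "occupancy": 2, "tss": 3,
            "interactions": 4, "coaccess": 5}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


@dataclass
class SyntheticTruth:
    """Planted ground truth, filled in by the generators as they run."""

    region_class: dict[str, str] = field(default_factory=dict)
    loop_degree: dict[str, int] = field(default_factory=dict)
    informative_factor: dict[str, bool] = field(default_factory=dict)
    library_sizes: dict[str, float] = field(default_factory=dict)

    def class_series(self) -> pd.Series:
        return pd.Series(self.region_class, name="true_class")


def allocate_counts(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Largest-remainder integer allocation of ``n`` items to proportions.

    Deterministic: floors first, then hands remaining units to the largest
    fractional parts (ties broken by earlier position).
    """
    exact = [n * p for p in proportions]
    counts = [int(np.floor(e)) for e in exact]
    remainder = n - sum(counts)
    order = sorted(range(len(exact)),
                   key=lambda i: (-(exact[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def simulate_regions(config: SimulationConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Place non-overlapping regions on the synthetic contig.

    Returns a region table (``chrom, start, end, region_id, group,
    true_class``; 0-based half-open coordinates) and a :class:`SyntheticTruth`
    holding the planted class labels. Clinical regions receive classes at
    ``class_proportions``; ARE-only and positive-control regions are
    labelled ``none``.
    """
    n_total = config.n_clinical + config.n_are_only + config.n_positive_ctrl
    if n_total == 0:
        raise ValueError("no regions requested")
    rng = _rng(config, "regions")
    width = config.region_width
    length = config.contig_length
    if length < n_total * width:
        raise RuntimeError("contig too small to place requested regions")

    starts: np.ndarray = np.empty(0, dtype=np.int64)
    for _ in range(200):
        need = n_total - starts.size
        if need <= 0:
            break
        cand = rng.integers(0, length - width, size=2 * need + 16)
        pool = np.sort(np.concatenate([starts, cand]))
        keep = [pool[0]]
        for s in pool[1:]:
            if s >= keep[-1] + width:
                keep.append(s)
        starts = np.asarray(keep[: n_total], dtype=np.int64)
    else:
        raise RuntimeError("rejection sampling failed to place regions")

    # shuffle placement order so genomic position is independent of group
    perm = rng.permutation(n_total)
    starts = starts[perm]
    groups = (["clinical"] * config.n_clinical
              + ["are_only"] * config.n_are_only
              + ["positive_ctrl"] * config.n_positive_ctrl)
    class_counts = allocate_counts(config.n_clinical, config.class_proportions)
    clinical_classes = np.repeat(list(CLASSES), class_counts)
    rng.shuffle(clinical_classes)
    labels = np.concatenate([clinical_classes,
                             np.repeat("none", n_total - config.n_clinical)])

    ids = [f"R{i + 1:06d}" for i in range(n_total)]
    regions = pd.DataFrame({
        "chrom": CHROM,
        "start": starts,
        "end": starts + width,
        "region_id": ids,
        "group": groups,
        "true_class": labels,
    })
    truth = SyntheticTruth(region_class=dict(zip(ids, labels)))
    return regions, truth


def _class_ratios(label: str, group: str, config: SimulationConfig) -> tuple[float, float]:
    """Planted (EtOH, DHT) RNA/plasmid mean ratios for one region."""
    dht_active = max(config.fc_induced, config.fc_active)
    if label == "inducible":
        return dht_active / config.fc_induced, dht_active
    if label == "constitutive":
        return config.fc_active, config.fc_active
    if label == "inactive":
        return 1.0, 1.0
    # untested groups: positive controls are active, ARE-only neutral
    if group == "positive_ctrl":
        return config.fc_active, config.fc_active
    return 1.0, 1.0


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + alpha mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_starr_counts(
    regions: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the STARR-seq count matrix for all regions.

    Returns ``(counts, roles)``: an integer region x sample matrix indexed
    by region_id, and a sample-role table with columns ``sample, role,
    condition`` (roles: plasmid / rna_etoh / rna_dht). Per-sample library
    size factors (log-normal, sigma 0.2) are recorded in
    ``truth.library_sizes``.
    """
    missing = [r for r in regions["region_id"] if r not in truth.region_class]
    if missing:
        raise ValueError(f"regions without planted class: {missing[:3]}...")
    rng = _rng(config, "counts")
    n_rep = config.n_replicates
    samples, roles, conditions = [], [], []
    for role, cond in (("plasmid", "input"), ("rna_etoh", "etoh"), ("rna_dht", "dht")):
        for i in range(n_rep):
            samples.append(f"{role}_{i + 1}")
            roles.append(role)
            conditions.append(cond)
    lib = np.exp(rng.normal(0.0, 0.2, size=len(samples)))
    truth.library_sizes = dict(zip(samples, lib))

    ratios = np.array([
        _class_ratios(truth.region_class[r], g, config)
        for r, g in zip(regions["region_id"], regions["group"])
    ])  # (n_regions, 2): EtOH, DHT
    role_ratio = {"plasmid": np.ones(len(regions)),
                  "rna_etoh": ratios[:, 0],
                  "rna_dht": ratios[:, 1]}
    counts = np.empty((len(regions), len(samples)), dtype=np.int64)
    for j, (s, role) in enumerate(zip(samples, roles)):
        mu = config.baseline_mean * role_ratio[role] * lib[j]
        counts[:, j] = _nb_draw(rng, mu, config.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=pd.Index(regions["region_id"], name="region_id"),
                             columns=samples)
    roles_df = pd.DataFrame({"sample": samples, "role": roles, "condition": conditions})
    return counts_df, roles_df


def simulate_occupancy(
    regions: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw raw occupancy scores and matched control scores.

    Null scores are Gamma(2, 1) per factor and region. The first
    ``informative_factors`` factors add ``occupancy_effect_sd`` null SDs at
    inducible regions; remaining factors are identically distributed across
    classes. The observed table has entries masked to NaN at
    ``missing_rate``; the control table is complete.
    """
    rng = _rng(config, "occupancy")
    n_regions = len(regions)
    factors = [f"F{i + 1:03d}" for i in range(config.n_factors)]
    shape, scale = 2.0, 1.0
    null_sd = np.sqrt(shape) * scale
    is_inducible = (regions["true_class"] == "inducible").to_numpy()

    observed = rng.gamma(shape, scale, size=(n_regions, config.n_factors))
    control = rng.gamma(shape, scale, size=(n_regions, config.n_factors))
    shift = config.occupancy_effect_sd * null_sd
    for k in range(config.informative_factors):
        observed[is_inducible, k] += shift
    if config.missing_rate > 0:
        mask = rng.random(size=observed.shape) < config.missing_rate
        observed[mask] = np.nan

    truth.informative_factor = {
        f: i < config.informative_factors for i, f in enumerate(factors)
    }
    idx = pd.Index(regions["region_id"], name="region_id")
    return (pd.DataFrame(observed, index=idx, columns=factors),
            pd.DataFrame(control, index=idx, columns=factors))


def simulate_tss(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a TSS table (``chrom, tss_pos, strand, gene, direction``).

    Direction labels (up / down / none) mark androgen up- and
    down-regulated differentially expressed genes; ``none`` genes are not
    differentially expressed and never become network nodes.
    """
    rng = _rng(config, "tss")
    n = config.n_tss
    pos = np.sort(rng.integers(0, config.contig_length, size=n))
    counts = allocate_counts(n, config.tss_direction_fractions)
    directions = np.repeat(["up", "down", "none"], counts)
    rng.shuffle(directions)
    return pd.DataFrame({
        "chrom": CHROM,
        "tss_pos": pos,
        "strand": rng.choice(["+", "-"], size=n),
        "gene": [f"G{i + 1:04d}" for i in range(n)],
        "direction": directions,
    })


def simulate_interactions(
    regions: pd.DataFrame,
    truth: SyntheticTruth,
    tss_table: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Generate a chromatin-loop anchor list (BEDPE-style table).

    Each region initiates ``Poisson(base_loop_degree * m)`` loops with
    ``m = hub_enrichment`` for inducible regions and 1 otherwise. A
    ``tss_edge_fraction`` of loops target a TSS anchor — biased toward
    up-DEG TSSs for inducible initiators — and the rest target another
    region drawn proportionally to its own initiation rate, so the
    realised mean loop degree of inducible regions is ``hub_enrichment``
    times the inactive mean. Realised degrees land in
    ``truth.loop_degree``.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    if not {"up", "down", "none"}.issuperset(tss_table["direction"].unique()):
        raise ValueError("tss_table direction labels must be up/down/none")
    rng = _rng(config, "interactions")
    ids = regions["region_id"].to_numpy()
    labels = regions["true_class"].to_numpy()
    rates = np.where(labels == "inducible",
                     config.base_loop_degree * config.hub_enrichment,
                     config.base_loop_degree)
    n_loops = rng.poisson(rates)
    p_partner = rates / rates.sum()

    up_idx = np.flatnonzero((tss_table["direction"] == "up").to_numpy())
    all_idx = np.arange(len(tss_table))
    starts = regions["start"].to_numpy()
    ends = regions["end"].to_numpy()
    tss_pos = tss_table["tss_pos"].to_numpy()

    rows = []
    degree = dict.fromkeys(ids, 0)
    pair_no = 0
    for i, k in enumerate(n_loops):
        for _ in range(k):
            degree[ids[i]] += 1
            if (len(all_idx) > 0) and (rng.random() < config.tss_edge_fraction):
                if (labels[i] == "inducible" and len(up_idx) > 0
                        and rng.random() < config.inducible_up_tss_bias):
                    t = int(rng.choice(up_idx))
                else:
                    t = int(rng.choice(all_idx))
                b_start = max(0, int(tss_pos[t]) - 250)
                b_end = int(tss_pos[t]) + 250
            else:
                j = int(rng.choice(len(ids), p=p_partner))
                degree[ids[j]] += 1
                b_start, b_end = int(starts[j]), int(ends[j])
            pair_no += 1
            rows.append((CHROM, int(starts[i]), int(ends[i]),
                         CHROM, b_start, b_end, f"loop{pair_no:06d}"))
    truth.loop_degree = degree
    return pd.DataFrame(rows, columns=["chrom_a", "start_a", "end_a",
                                       "chrom_b", "start_b", "end_b", "pair_id"])


def simulate_coaccessibility(
    regions: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate scored co-accessibility pair lists for EtOH and DHT.

    Base scores are Uniform(0, 0.2) shared between conditions. Pairs with
    at least one inducible endpoint gain ``coaccess_gain`` under DHT
    (clipped to [0, 1]); other pairs differ only by ``coaccess_noise``.
    Columns: ``region_a, region_b, score``.
    """
    rng = _rng(config, "coaccess")
    ids = regions["region_id"].to_numpy()
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two regions for pairs")
    n_pairs = int(round(config.coaccess_pairs_per_region * n))
    seen: set[tuple[int, int]] = set()
    pairs = []
    while len(pairs) < n_pairs:
        a, b = rng.integers(0, n, size=2)
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        pairs.append(key)
    pairs_arr = np.asarray(pairs)
    base = rng.uniform(0.0, 0.2, size=len(pairs))
    labels = regions["true_class"].to_numpy()
    adj_inducible = ((labels[pairs_arr[:, 0]] == "inducible")
                     | (labels[pairs_arr[:, 1]] == "inducible"))
    dht = base.copy()
    if config.coaccess_noise > 0:
        dht = dht + rng.normal(0.0, config.coaccess_noise, size=len(pairs))
    dht[adj_inducible] += config.coaccess_gain
    dht = np.clip(dht, 0.0, 1.0)

    def table(scores: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({
            "region_a": ids[pairs_arr[:, 0]],
            "region_b": ids[pairs_arr[:, 1]],
            "score": scores,
        })

    return table(base), table(dht)
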