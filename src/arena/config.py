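"""Configuration objects for the synthetic-data generators.

The defaults encode the study conditions the pipeline is designed around:
4139 clinical AR binding sites of which 6.9% are inducible, 11.2%
constitutive and 81.9% inactive enhancers, three biological replicates per
condition, fourfold activity effects, and 90 DNA-binding factors of which a
handful carry class-dependent signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic region/count/occupancy/network generators.

    Attributes
    ----------
    n_clinical, n_are_only, n_positive_ctrl:
        Sizes of the three design groups: clinical AR binding sites (the
        regions that receive a planted enhancer class), regions with an
        androgen-response-element motif but no AR binding, and non-AR
        positive-control enhancers.
    class_proportions:
        Fractions of clinical regions planted as (inducible, constitutive,
        inactive); must sum to 1.
    n_replicates:
        Biological replicates per sample role (plasmid, RNA-EtOH, RNA-DHT).
    baseline_mean:
        Expected plasmid-normalised count for a neutral region.
    fc_induced:
        Mean RNA fold change DHT vs EtOH planted at inducible regions.
    fc_active:
        RNA/plasmid fold change planted at active (constitutive and
        positive-control) regions in both conditions.
    nb_dispersion:
        Negative-binomial dispersion alpha in the mean–dispersion
        parameterisation var = mu + alpha * mu**2; 0 gives Poisson counts.
    n_factors, informative_factors:
        Number of occupancy features and how many of them carry a
        class-dependent shift (planted for the inducible class).
    occupancy_effect_sd:
        Size of that shift in units of the null-score standard deviation.
    missing_rate:
        Bernoulli rate of missing entries in the observed occupancy table.
    hub_enrichment:
        Multiplier on the loop-initiation rate of inducible regions; 1
        plants no hub structure.
    base_loop_degree:
        Poisson mean of loops initiated per non-inducible region.
    tss_edge_fraction:
        Fraction of initiated loops whose partner anchor is a TSS.
    inducible_up_tss_bias:
        Probability that a TSS partner of an inducible region is an
        up-regulated-gene TSS (others choose TSS uniformly).
    n_tss:
        Number of simulated TSSs; direction labels up/down/none are drawn
        with ``tss_direction_fractions``.
    coaccess_pairs_per_region:
        Density of the scored co-accessibility pair list.
    coaccess_gain:
        Additive score gain under DHT for pairs adjacent to an inducible
        region (clipped to [0, 1]).
    coaccess_noise:
        SD of condition-independent score noise added to the DHT list for
        non-planted pairs; 0 keeps both conditions identical off-target.
    region_width, genome_length:
        Interval width and synthetic contig size; ``genome_length=None``
        auto-sizes the contig to keep rejection sampling cheap.
    seed:
        Root seed; every generator derives independent streams from it.
    """

    n_clinical: int = 4139
    n_are_only: int = 2783
    n_positive_ctrl: int = 500
    class_proportions: tuple[float, float, float] = (0.069, 0.112, 0.819)
    n_replicates: int = 3
    baseline_mean: float = 200.0
    fc_induced: float = 4.0
    fc_active: float = 4.0
    nb_dispersion: float = 0.05
    n_factors: int = 90
    informative_factors: int = 5
    occupancy_effect_sd: float = 3.0
    missing_rate: float = 0.1
    hub_enrichment: float = 3.0
    base_loop_degree: float = 1.0
    tss_edge_fraction: float = 0.3
    inducible_up_tss_bias: float = 0.7
    n_tss: int = 300
    tss_direction_fractions: tuple[float, float, float] = (0.4, 0.3, 0.3)
    coaccess_pairs_per_region: float = 3.0
    coaccess_gain: float = 0.3
    coaccess_noise: float = 0.0
    region_width: int = 600
    genome_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_clinical", "n_are_only", "n_positive_ctrl",
                     "n_replicates", "n_factors", "n_tss", "region_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_clinical + self.n_are_only + self.n_positive_ctrl == 0:
            raise ValueError("at least one region must be requested")
        props = self.class_proportions
        if len(props) != 3 or any(p < 0 or p > 1 for p in props):
            raise ValueError("class_proportions must be three fractions in [0, 1]")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1 within 1e-9")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.informative_factors > self.n_factors:
            raise ValueError("informative_factors cannot exceed n_factors")
        if self.coaccess_gain < 0:
            raise ValueError("coaccess_gain must be >= 0")
        if self.region_width < 500:
            raise ValueError("regions must be at least 500 bp")

    def replace(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields overridden."""
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return SimulationConfig(**current)

    @property
    def contig_length(self) -> int:
        if self.genome_length is not None:
            return self.genome_length
        n = self.n_clinical + self.n_are_only + self.n_positive_ctrl
        # 20x occupancy head-room keeps rejection sampling near one pass
        return max(1_000_000, 20 * n * self.region_width)


CHROM = "chrS"
CLASSES = ("inducible", "constitutive", "inactive")
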