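"""Synthetic single-cell and droplet-PCR data with known ground truth.

The expression generator emulates the statistical structure the LOY
analysis relies on: male and female donors; a Treg/Th/CTL/other cell-type
mixture per tissue; per-(tissue, cell type) true LOY fractions; six
male-specific-region (MSY) genes whose counts are structurally zero in
female-donor cells and in cells that truly lost chromosome Y; technical
dropout on the MSY genes in Y-bearing cells; marker genes elevated in
their defining type; and configurable additive mean shifts of
immunosuppressive genes (PDCD1, TIGIT, IKZF2) in LOY Tregs.

Count model
-----------
Counts are negative binomial with dispersion ``theta``
(var = mu + mu^2/theta).  MSY genes in Y-bearing cells use a
*zero-truncated* negative binomial mixed with an independent per-gene
technical-zero probability ``msy_dropout``, so that
P(count = 0 | Y-bearing cell) equals the configured dropout exactly and
the analytic false-positive rate of the zero-expression LOY rule is the
plain product of per-gene dropouts.

Randomness is a single seed split hierarchically (gene-level stream, then
one stream per donor), so adding donors never perturbs the draws of
existing donors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, DropletWell, TISSUES, ValidationError

DEFAULT_MSY_PANEL = ("RPS4Y1", "ZFY", "USP9Y", "DDX3Y", "KDM5D", "EIF1AY")
MARKER_GENES = ("CTLA4", "IL23R", "CD4", "CD8A")
IMMUNOSUPPRESSIVE_GENES = (
    "CTLA4", "PDCD1", "HAVCR2", "LAG3", "TIGIT", "ICOS",   # IC receptors
    "ENTPD1", "NT5E", "CD80",                               # APC manipulation
    "CCR1", "CCR4", "CCR5", "CCR7", "CCR8",                 # migration
    "IKZF2",                                                # Helios TF
)

#: Default true LOY fractions per (tissue, cell type): tumor values follow
#: the reported Treg 22% / Th 11% / CTL 14%; blood follows the sorted-cell
#: ddPCR means (Treg 17%, Th 4%, CTL 4%); margins are uniformly low.
DEFAULT_LOY_FRACTIONS = {
    ("tumor", "Treg"): 0.22, ("tumor", "Th"): 0.11, ("tumor", "CTL"): 0.14,
    ("tumor", "other"): 0.10,
    ("UM", "Treg"): 0.05, ("UM", "Th"): 0.04, ("UM", "CTL"): 0.05,
    ("UM", "other"): 0.04,
    ("blood", "Treg"): 0.17, ("blood", "Th"): 0.04, ("blood", "CTL"): 0.04,
    ("blood", "other"): 0.08,
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Conditions for one synthetic single-cell experiment.

    Parameters
    ----------
    n_donors, donor_sexes
        Cohort size and per-donor sex ("male"/"female").  Defaults to the
        four-male-patient design of the primary cohort.
    cell_type_props
        Mixture over Treg/Th/CTL/other.  The default puts Tregs at 25% of
        the CD4 compartment, inside the 10-50% range reported for
        tumor-infiltrating Tregs.
    loy_fraction
        (tissue, cell_type) -> true LOY probability for male donors.
        Female donors have zero LOY by construction.
    msy_mean_expression, msy_dropout
        Per-MSY-gene negative-binomial mean and technical-zero
        probability in Y-bearing cells (scalars broadcast to all six).
    module_effect
        gene -> additive shift of the negative-binomial mean in truth-LOY
        Tregs, emulating the immunosuppressive up-regulation the analysis
        should detect.
    dispersion
        Negative-binomial size parameter theta; var = mu + mu^2/theta.
    mask_cd4_subtypes
        When true, Treg/Th cells are emitted with cell_type
        "unassigned" so the annotation stage has work to do; truth_type
        always carries the real label.
    """

    n_donors: int = 4
    donor_sexes: tuple = None
    tissues: tuple = TISSUES
    cell_type_props: dict = field(
        default_factory=lambda: {"Treg": 0.15, "Th": 0.45, "CTL": 0.25, "other": 0.15}
    )
    loy_fraction: dict = field(default_factory=lambda: dict(DEFAULT_LOY_FRACTIONS))
    n_cells_per_donor_tissue: int = 500
    n_filler_genes: int = 200
    msy_mean_expression: float | dict = 2.0
    msy_dropout: float | dict = 0.1
    module_effect: dict = field(
        default_factory=lambda: {"PDCD1": 0.5, "TIGIT": 0.5, "IKZF2": 0.5}
    )
    dispersion: float = 2.0
    marker_boost: float = 3.0
    treg_program_boost: float = 1.0
    seed: int = 0
    mask_cd4_subtypes: bool = False
    loy_fraction_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.donor_sexes is None:
            self.donor_sexes = ("male",) * self.n_donors
        self.donor_sexes = tuple(self.donor_sexes)
        if len(self.donor_sexes) != self.n_donors:
            raise ConfigError("donor_sexes length must equal n_donors")
        if any(s not in ("male", "female") for s in self.donor_sexes):
            raise ConfigError("donor sexes must be 'male' or 'female'")
        total = sum(self.cell_type_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"cell_type_props must sum to 1 (got {total})")
        for key, p in {**self.loy_fraction,
                       **{("dropout", g): q for g, q in self._per_gene(self.msy_dropout).items()}}.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability out of range for {key}: {p}")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        for donor, frac in self.loy_fraction_overrides.items():
            idx = int(donor) if not str(donor).startswith("D") else int(str(donor)[1:]) - 1
            if self.donor_sexes[idx] == "female" and any(v > 0 for v in dict(frac).values()):
                raise ConfigError(
                    f"female donor {donor!r} cannot be assigned a nonzero LOY fraction"
                )

    def _per_gene(self, value) -> dict:
        if isinstance(value, dict):
            return {g.upper(): float(v) for g, v in value.items()}
        return {g: float(value) for g in DEFAULT_MSY_PANEL}

    @property
    def msy_means(self) -> dict:
        return self._per_gene(self.msy_mean_expression)

    @property
    def msy_dropouts(self) -> dict:
        return self._per_gene(self.msy_dropout)


def analytic_false_positive_rate(config: SimulationConfig) -> float:
    """P(zero-expression LOY call | Y-bearing cell): product of per-gene
    zero probabilities, which under the truncated-NB model is the product
    of the configured dropouts."""
    rate = 1.0
    for q in config.msy_dropouts.values():
        rate *= q
    return rate


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Negative-binomial counts with mean mu, size theta (elementwise)."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        p = theta / (theta + mu[pos])
        out[pos] = rng.negative_binomial(theta, p)
    return out


def _truncated_nb_draw(rng: np.random.Generator, mu: float, theta: float, size: int) -> np.ndarray:
    """Zero-truncated NB via resampling of zero draws."""
    if size == 0:
        return np.zeros(0, dtype=np.int64)
    p = theta / (theta + mu)
    draws = rng.negative_binomial(theta, p, size=size)
    zero = draws == 0
    while zero.any():
        draws[zero] = rng.negative_binomial(theta, p, size=int(zero.sum()))
        zero = draws == 0
    return draws


def gene_panel(config: SimulationConfig) -> list[str]:
    """Ordered, de-duplicated gene list of the synthetic matrix."""
    genes: list[str] = []
    for g in (*DEFAULT_MSY_PANEL, *MARKER_GENES, *IMMUNOSUPPRESSIVE_GENES):
        if g not in genes:
            genes.append(g)
    genes.extend(f"FILLER{i + 1:04d}" for i in range(config.n_filler_genes))
    return genes


def generate_expression_dataset(config: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw one synthetic cohort: counts plus a cell table with truth labels.

    Returns a genes x cells :class:`CountMatrix` and a cell table with
    columns cell_id, donor_id, tissue, cell_type, loy_call, donor_sex,
    truth_type, truth_loy.  Deterministic under a fixed config seed.
    """
    genes = gene_panel(config)
    gene_pos = {g: i for i, g in enumerate(genes)}
    types = list(config.cell_type_props)
    props = np.array([config.cell_type_props[t] for t in types], dtype=float)
    theta = config.dispersion

    root = np.random.SeedSequence(config.seed)
    gene_ss, *donor_ss = root.spawn(1 + config.n_donors)

    # per-gene baseline rates; filler means are log-normal so control bins
    # span the expression range
    gene_rng = np.random.default_rng(gene_ss)
    base_mu = np.full(len(genes), 0.2)
    for g in config.msy_means:
        if g in gene_pos:
            base_mu[gene_pos[g]] = config.msy_means[g]
    for g in IMMUNOSUPPRESSIVE_GENES:
        base_mu[gene_pos[g]] = 0.5
    filler_idx = np.array([gene_pos[g] for g in genes if g.startswith("FILLER")], dtype=int)
    base_mu[filler_idx] = gene_rng.lognormal(mean=-1.0, sigma=1.0, size=filler_idx.size)

    marker_targets = {"CTLA4": ("Treg",), "IL23R": ("Treg",),
                      "CD4": ("Treg", "Th"), "CD8A": ("CTL",)}
    msy_idx = {g: gene_pos[g] for g in config.msy_means if g in gene_pos}

    blocks: list[np.ndarray] = []
    rows = []
    for d, ss in enumerate(donor_ss):
        donor_id = f"D{d + 1:02d}"
        sex = config.donor_sexes[d]
        rng = np.random.default_rng(ss)
        for tissue in config.tissues:
            n = config.n_cells_per_donor_tissue
            type_idx = rng.choice(len(types), size=n, p=props)
            cell_types = np.array(types, dtype=object)[type_idx]
            loy_p = np.array(
                [config.loy_fraction.get((tissue, t), 0.0) for t in cell_types]
            )
            if sex == "female":
                loy_p = np.zeros(n)
            truth_loy = rng.random(n) < loy_p

            mu = np.tile(base_mu, (n, 1))
            for marker, targets in marker_targets.items():
                mask = np.isin(cell_types, targets)
                mu[mask, gene_pos[marker]] += config.marker_boost
            # tumor-infiltrating Tregs elevate the immunosuppressive program
            # broadly (CCR8, CCR4, IKZF2, ICOS, ENTPD1, ...), not only the
            # two classifier markers
            treg_mask = cell_types == "Treg"
            for g in IMMUNOSUPPRESSIVE_GENES:
                mu[treg_mask, gene_pos[g]] += config.treg_program_boost
            for g, delta in config.module_effect.items():
                g = g.upper()
                if g in gene_pos:
                    mask = truth_loy & (cell_types == "Treg")
                    mu[mask, gene_pos[g]] += float(delta)

            counts = _nb_draw(rng, mu, theta)

            # MSY genes: structural zeros for female / truth-LOY cells,
            # dropout-mixed zero-truncated NB otherwise
            y_bearing = np.flatnonzero(~truth_loy) if sex == "male" else np.array([], dtype=int)
            counts[:, list(msy_idx.values())] = 0
            for g, j in msy_idx.items():
                if y_bearing.size:
                    kept = y_bearing[rng.random(y_bearing.size) >= config.msy_dropouts[g]]
                    counts[kept, j] = _truncated_nb_draw(
                        rng, config.msy_means[g], theta, kept.size
                    )

            blocks.append(counts)
            for i in range(n):
                observed = cell_types[i]
                if config.mask_cd4_subtypes and observed in ("Treg", "Th"):
                    observed = "unassigned"
                rows.append(
                    {
                        "cell_id": f"{donor_id}_{tissue}_{i + 1:05d}",
                        "donor_id": donor_id,
                        "tissue": tissue,
                        "cell_type": observed,
                        "loy_call": "unassigned",
                        "donor_sex": sex,
                        "truth_type": cell_types[i],
                        "truth_loy": bool(truth_loy[i]),
                    }
                )

    cells = pd.DataFrame(rows)
    values = sp.csr_matrix(np.vstack(blocks).T)  # genes x cells
    matrix = CountMatrix(values, np.array(genes, dtype=object),
                         cells["cell_id"].to_numpy(dtype=object))
    return matrix, cells


# ---------------------------------------------------------------------------
# droplet digital PCR


@dataclass
class DropletExperimentConfig:
    """One simulated two-channel droplet well.

    X-template copies per droplet are Poisson(lambda_g); Y-template copies
    are Poisson(lambda_g * (1 - f)) with f = true_loy_pct / 100.  A droplet
    is channel-positive iff it holds >= 1 copy of that template.
    """

    true_loy_pct: float = 10.0
    n_droplets: int = 20000
    mean_genomes_per_droplet: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_loy_pct <= 100.0:
            raise ConfigError("true_loy_pct must be in [0, 100]")
        if self.n_droplets <= 0:
            raise ConfigError("n_droplets must be positive")
        if self.mean_genomes_per_droplet <= 0:
            raise ConfigError("mean_genomes_per_droplet must be positive")


def generate_ddpcr_experiment(
    config: DropletExperimentConfig, sample_id: str = "sim"
) -> tuple[DropletWell, dict]:
    """Simulate droplet partitioning and return the well plus a truth record."""
    rng = np.random.default_rng(config.seed)
    lam = config.mean_genomes_per_droplet
    f = config.true_loy_pct / 100.0
    x_copies = rng.poisson(lam, size=config.n_droplets)
    y_copies = rng.poisson(lam * (1.0 - f), size=config.n_droplets)
    well = DropletWell(
        sample_id=sample_id,
        n_total=config.n_droplets,
        n_pos_x=int((x_copies > 0).sum()),
        n_pos_y=int((y_copies > 0).sum()),
    )
    truth = {"true_loy_pct": config.true_loy_pct, "lambda_x": lam, "lambda_y": lam * (1.0 - f)}
    return well, truth
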