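"""Seed-deterministic generators for every analysis stage.

The scRNA-seq generator draws negative-binomial UMI counts for cells that
carry (i) a subpopulation identity with a subpopulation-specific gene
program, (ii) a cell-cycle stage with S / G2M marker programs, and (iii) a
treatment-arm origin that reweights subpopulation frequencies — emulating a
three-arm perturbation experiment in which one rare subpopulation is
selectively depleted by the active probe (default multiplier 0.2, i.e. an
~80% depletion) while a control compound leaves it untouched.  Ground-truth
subpopulation and stage labels travel with the counts so recovery can be
scored.

Companion generators produce LC-MS/MS peak tables (forward model of the
working-curve/weighting/volume chain) and dose-response / melt tables
(forward evaluation plus multiplicative noise) for the quantification and
fitting modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .lcms import CellExtract
from .preprocess import make_count_matrix

__all__ = [
    "SubpopSpec",
    "StageProgram",
    "ScSimConfig",
    "default_config",
    "simulate_counts",
    "simulate_lcms",
    "simulate_doseresponse",
]


@dataclass(frozen=True)
class SubpopSpec:
    """A subpopulation: its name, gene program (gene index → log-fold
    effect on the mean) and frequency in the vehicle arm."""

    name: str
    program: Mapping[int, float]
    base_frequency: float


@dataclass(frozen=True)
class StageProgram:
    """Marker gene indices and the log-fold effect applied in that stage."""

    genes: tuple[int, ...]
    # Cycle markers are close to on/off between stages in droplet data;
    # an ~8-fold swing is the realistic regime.
    effect: float = np.log(8.0)


@dataclass(frozen=True)
class ScSimConfig:
    """Study design for the scRNA-seq count generator.

    ``origins`` maps each treatment arm to per-subpopulation frequency
    multipliers (missing subpopulations default to 1.0); frequencies are
    renormalized per arm.  ``stage_frequencies`` gives the marginal
    cell-cycle stage distribution, shared across arms.  Library sizes are
    log-normal; counts are negative binomial with a shared dispersion.
    """

    n_genes: int
    subpopulations: tuple[SubpopSpec, ...]
    origins: Mapping[str, Mapping[str, float]]
    s_program: StageProgram
    g2m_program: StageProgram
    stage_frequencies: Mapping[str, float] = field(
        default_factory=lambda: {"G0/G1": 0.631, "S": 0.139, "G2/M": 0.230}
    )
    library_mu: float = np.log(8000.0)
    library_sigma: float = 0.25
    nb_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        base = np.array([s.base_frequency for s in self.subpopulations])
        if np.any(base <= 0) or not np.isclose(base.sum(), 1.0):
            raise ValueError("base frequencies must be positive and sum to 1")
        sf = np.array(list(self.stage_frequencies.values()))
        if np.any(sf < 0) or not np.isclose(sf.sum(), 1.0):
            raise ValueError("stage frequencies must be a probability vector")
        names = {s.name for s in self.subpopulations}
        for origin, mult in self.origins.items():
            unknown = set(mult) - names
            if unknown:
                raise ValueError(f"origin {origin!r} references unknown subpopulations {unknown}")

    def origin_frequencies(self, origin: str) -> np.ndarray:
        """Renormalized subpopulation frequencies in one arm."""
        mult = self.origins[origin]
        f = np.array([s.base_frequency * mult.get(s.name, 1.0) for s in self.subpopulations])
        return f / f.sum()


def default_config(
    n_genes: int = 1500,
    n_program_genes: int = 40,
    n_stage_genes: int = 40,
    program_effect: float = np.log(3.0),
    probe_multiplier: float = 0.2,
    seed: int = 0,
) -> ScSimConfig:
    """Three-arm design with five subpopulations, one probe-depleted.

    Subpopulation frequencies 0.30/0.25/0.20/0.17/0.08 in the vehicle arm;
    the rare 8% subpopulation (``invasion_prone``) carries the probe-arm
    multiplier (default 0.2).  Gene programs occupy disjoint index blocks at
    the front of the gene vector, followed by the S and G2M marker blocks.
    """
    freqs = [0.30, 0.25, 0.20, 0.17, 0.08]
    names = ["sub0", "sub1", "sub2", "sub3", "invasion_prone"]
    needed = len(freqs) * n_program_genes + 2 * n_stage_genes
    if needed > n_genes:
        raise ValueError(f"n_genes={n_genes} too small for the programs ({needed} needed)")

    subpops = []
    pos = 0
    for name, f in zip(names, freqs):
        block = range(pos, pos + n_program_genes)
        subpops.append(SubpopSpec(name, {g: program_effect for g in block}, f))
        pos += n_program_genes
    s_prog = StageProgram(tuple(range(pos, pos + n_stage_genes)))
    pos += n_stage_genes
    g2m_prog = StageProgram(tuple(range(pos, pos + n_stage_genes)))

    origins = {
        "vehicle": {},
        "control": {},
        "probe": {"invasion_prone": probe_multiplier},
    }
    return ScSimConfig(
        n_genes=n_genes,
        subpopulations=tuple(subpops),
        origins=origins,
        s_program=s_prog,
        g2m_program=g2m_prog,
        seed=seed,
    )


def simulate_counts(cfg: ScSimConfig, n_cells: Mapping[str, int]) -> ad.AnnData:
    """Draw a UMI count matrix with ground-truth labels.

    ``n_cells`` maps origin name → number of cells.  Per cell: the
    subpopulation is drawn from the arm's frequencies, the stage from the
    stage marginals, and the library factor from the log-normal; the mean of
    gene g is baseline_g × exp(program effects) scaled to the library size,
    and the count is negative binomial (gamma–Poisson) with the configured
    dispersion.  Returns an AnnData with ``obs`` columns ``origin``,
    ``subpopulation`` and ``stage`` (ground truth).  Byte-identical for a
    given config and ``n_cells``.
    """
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    subpops = cfg.subpopulations
    stages = list(cfg.stage_frequencies)
    stage_p = np.array(list(cfg.stage_frequencies.values()))

    # Baseline relative expression: heavy-tailed, as in real transcriptomes.
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=G)
    baseline /= baseline.sum()

    # Per-subpopulation and per-stage multiplicative effect vectors.
    sub_factor = np.ones((len(subpops), G))
    for k, s in enumerate(subpops):
        for g, eff in s.program.items():
            sub_factor[k, g] = np.exp(eff)
    stage_factor = {st: np.ones(G) for st in stages}
    for st, prog in (("S", cfg.s_program), ("G2/M", cfg.g2m_program)):
        if st in stage_factor:
            stage_factor[st][list(prog.genes)] = np.exp(prog.effect)

    blocks, sub_labels, stage_labels, origin_labels = [], [], [], []
    # arms drawn in sorted name order so the result is independent of the
    # mapping's insertion order (configs may round-trip through sorted YAML)
    for origin in sorted(n_cells):
        n = n_cells[origin]
        freqs = cfg.origin_frequencies(origin)
        sub_idx = rng.choice(len(subpops), size=n, p=freqs)
        stage_idx = rng.choice(len(stages), size=n, p=stage_p)
        lib = rng.lognormal(mean=cfg.library_mu, sigma=cfg.library_sigma, size=n)

        mean = sub_factor[sub_idx] * np.stack([stage_factor[stages[i]] for i in stage_idx])
        mean *= baseline
        mean *= (lib / mean.sum(axis=1))[:, None]

        shape = cfg.nb_dispersion
        lam = rng.gamma(shape=shape, scale=mean / shape)
        blocks.append(rng.poisson(lam).astype(np.int64))
        sub_labels.extend(subpops[i].name for i in sub_idx)
        stage_labels.extend(stages[i] for i in stage_idx)
        origin_labels.extend([origin] * n)

    counts = np.vstack(blocks)
    gene_names = [f"G{i:05d}" for i in range(G)]
    barcodes = [f"cell{i:06d}" for i in range(counts.shape[0])]
    adata = make_count_matrix(counts, gene_names, barcodes, origin_labels)
    adata.obs["subpopulation"] = pd.Categorical(sub_labels)
    adata.obs["stage"] = pd.Categorical(stage_labels)
    adata.uns["simulation"] = {
        "seed": cfg.seed,
        "s_marker_genes": [gene_names[i] for i in cfg.s_program.genes],
        "g2m_marker_genes": [gene_names[i] for i in cfg.g2m_program.genes],
    }
    return adata


def simulate_lcms(
    true_concs: Sequence[float],
    p: float,
    q: float,
    noise_cv: float = 0.02,
    seed: int = 0,
    extract: CellExtract | None = None,
    c_is: float = 2.0,
    n_standards: int = 3,
    base_is_area: float = 1e6,
) -> pd.DataFrame:
    """Forward-model intracellular concentrations into an LC-MS/MS peak table.

    Each true intracellular concentration is mapped back to the extract
    concentration (inverse of the volume conversion), to the concentration
    ratio against ``c_is``, and through the working curve to a peak-area
    ratio; ``n_standards`` internal-standard measurements per sample get
    independent multiplicative Gaussian noise of CV ``noise_cv``.  Long
    format: sample, internal_standard, peak_area_analyte, peak_area_is,
    conc_is.
    """
    if p == 0:
        raise ValueError("working-curve slope p must be nonzero")
    extract = extract or CellExtract()
    rng = np.random.default_rng(seed)
    rows = []
    for s, c_intra in enumerate(true_concs):
        c_bar = c_intra * extract.cell_count * extract.mean_cell_volume / extract.extract_volume
        x_true = (c_bar / c_is - q) / p
        for k in range(n_standards):
            p_is = base_is_area * (1.0 + noise_cv * rng.standard_normal())
            p_a = x_true * base_is_area * (1.0 + noise_cv * rng.standard_normal())
            rows.append(
                {
                    "sample": s,
                    "internal_standard": f"IS{k + 1}",
                    "peak_area_analyte": p_a,
                    "peak_area_is": p_is,
                    "conc_is": c_is,
                }
            )
    return pd.DataFrame(rows)


def simulate_doseresponse(
    model: str,
    params: Mapping[str, float],
    doses: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Forward-evaluate a response model with noise.

    ``model`` is ``"saturation"`` (params ``max_effect_pct``, ``ec50``),
    ``"sigmoid"`` (``ic50``, ``hill``, optional ``floor``/``ceiling``) or
    ``"boltzmann"`` (``tm``, ``slope``, optional ``floor``/``ceiling``;
    doses are temperatures).  ``noise_cv`` adds multiplicative Gaussian
    noise (signal-proportional, as in peak-area readouts); ``noise_sd``
    adds homoscedastic Gaussian noise on the response scale.  Columns:
    dose, response.
    """
    x = np.asarray(doses, dtype=float)
    if model == "saturation":
        y = params["max_effect_pct"] * x / (x + params["ec50"])
    elif model == "sigmoid":
        floor = params.get("floor", 0.0)
        ceiling = params.get("ceiling", 100.0)
        hill = params.get("hill", 1.0)
        y = floor + (ceiling - floor) / (
            1.0 + 10.0 ** ((np.log10(params["ic50"]) - np.log10(x)) * hill)
        )
    elif model == "boltzmann":
        floor = params.get("floor", 0.0)
        ceiling = params.get("ceiling", 100.0)
        y = floor + (ceiling - floor) / (1.0 + np.exp((params["tm"] - x) / params["slope"]))
    else:
        raise ValueError(f"unknown model {model!r}")
    if noise_cv or noise_sd:
        rng = np.random.default_rng(seed)
        if noise_cv:
            y = y * (1.0 + noise_cv * rng.standard_normal(y.shape))
        if noise_sd:
            y = y + noise_sd * rng.standard_normal(y.shape)
    return pd.DataFrame({"dose": x, "response": y})
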