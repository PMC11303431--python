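"""Synthetic cohorts with planted co-expression and trait structure.

The generator emulates the statistical shape of a plaque-transcriptomics
cohort at desk scale: a few dozen samples, a handful of latent
co-expression modules, a majority of unstructured noise features, and
quantitative histological traits tied to chosen module factors at a
configurable correlation.  Every draw records its ground truth
(membership, loadings, factors, trait links), which is what makes each
pipeline stage testable without any download.

Model: one standard-normal latent factor f_m per module; a feature g of
module m is x_g = beta_g * f_m + eps, eps ~ N(0, noise_sd^2), so the
population within-module correlation is beta^2 / (beta^2 + noise_sd^2)
(0.64 at the default beta = 0.8, noise_sd = 0.6).  A linked trait is
rho * f_m + sqrt(1 - rho^2) * noise, giving population correlation
exactly rho with the factor.  The peptide generator plants linear,
parabolic (zero Pearson by symmetry) and sinusoidal functions of a
target trait among pure-noise features for the dual PCC/MIC ranking.

The default cohort is 40 samples, 5 modules x 50 features plus 750
noise features — mirroring the 22-43-patient scale of the cohorts this
pipeline is meant for while keeping test runs at seconds scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_N_SAMPLES = 40
DEFAULT_MODULE_SIZES = (50, 50, 50, 50, 50)
DEFAULT_LOADING = 0.8
DEFAULT_NOISE_SD = 0.6
DEFAULT_N_NOISE = 750

NOISE_LABEL = "noise"


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a synthetic draw."""

    membership: pd.Series = field(default_factory=pd.Series)   # feature -> module/noise
    loadings: pd.Series = field(default_factory=pd.Series)     # feature -> beta_g
    factors: pd.DataFrame = field(default_factory=pd.DataFrame)  # samples x modules
    trait_links: dict[str, tuple[str, float]] = field(default_factory=dict)
    peptide_classes: pd.Series = field(default_factory=pd.Series)
    noise_sd: float = 0.0
    seed: int = 0
    generator: str = "numpy.random.Generator(PCG64)"


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def generate_modular_expression(
        n_samples: int = DEFAULT_N_SAMPLES,
        module_sizes: tuple[int, ...] = DEFAULT_MODULE_SIZES,
        loading: float = DEFAULT_LOADING,
        noise_sd: float = DEFAULT_NOISE_SD,
        n_noise_features: int = DEFAULT_N_NOISE,
        seed: int = 0,
        hub_loading: float | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw an expression matrix with planted latent-factor modules.

    All features are standardized (mean 0, unit sample variance) on
    output, as a normalized expression matrix would be.  When
    ``hub_loading`` is given, the first feature of each module is a
    planted hub whose population correlation with the module factor is
    ``hub_loading`` exactly (x = beta*f + sqrt(1 - beta^2)*eps), a
    higher-fidelity copy of the factor than the regular members, whose
    factor correlation is loading / sqrt(loading^2 + noise_sd^2).
    """
    if n_samples < 8:
        raise ValueError("need at least 8 samples")
    if not 0 < loading <= 1:
        raise ValueError("loading must lie in (0, 1]")
    if hub_loading is not None and not 0 < hub_loading <= 1:
        raise ValueError("hub_loading must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    n_modules = len(module_sizes)
    factors = rng.standard_normal((n_samples, n_modules))
    module_labels = [f"M{m + 1}" for m in range(n_modules)]

    columns, membership, loadings = [], {}, {}
    blocks = []
    for m, size in enumerate(module_sizes):
        betas = np.full(size, float(loading))
        eps = rng.normal(0.0, noise_sd, size=(n_samples, size))
        block = factors[:, [m]] * betas[None, :] + eps
        if hub_loading is not None and size:
            betas[0] = float(hub_loading)
            hub_eps = rng.standard_normal(n_samples)
            block[:, 0] = (hub_loading * factors[:, m]
                           + np.sqrt(1.0 - hub_loading**2) * hub_eps)
        blocks.append(block)
        for g in range(size):
            name = f"G{len(columns) + 1:05d}"
            columns.append(name)
            membership[name] = module_labels[m]
            loadings[name] = float(betas[g])
    noise = rng.standard_normal((n_samples, n_noise_features))
    blocks.append(noise)
    for _ in range(n_noise_features):
        name = f"G{len(columns) + 1:05d}"
        columns.append(name)
        membership[name] = NOISE_LABEL
        loadings[name] = 0.0

    values = np.concatenate(blocks, axis=1)
    values = (values - values.mean(axis=0)) / values.std(axis=0, ddof=1)
    matrix = pd.DataFrame(values, index=_sample_ids(n_samples), columns=columns)
    matrix.index.name = "sample_id"
    matrix.columns.name = "feature_id"

    truth = SyntheticTruth(
        membership=pd.Series(membership, name="module"),
        loadings=pd.Series(loadings, name="loading"),
        factors=pd.DataFrame(factors, index=matrix.index, columns=module_labels),
        noise_sd=float(noise_sd),
        seed=int(seed),
    )
    return matrix, truth


def generate_traits(truth: SyntheticTruth,
                    links: dict[str, tuple[str, float]] | None = None,
                    n_null_traits: int = 4,
                    missing_rate: float = 0.0,
                    seed: int = 0) -> pd.DataFrame:
    """Draw a trait table tied to planted module factors.

    ``links`` maps trait name -> (module label, rho); a linked trait is
    rho * f_m + sqrt(1 - rho^2) * N(0, 1), so its population
    correlation with the factor is exactly rho.  Null traits are
    independent standard normal.  ``missing_rate`` masks cells missing
    at random.
    """
    if links is None:
        links = {"MVD": ("M1", 0.7)}
    rng = np.random.default_rng(seed)
    n = len(truth.factors.index)
    table = {}
    for trait, (module, rho) in links.items():
        if module not in truth.factors.columns:
            raise KeyError(f"trait {trait!r} links to unknown module {module!r}")
        if abs(rho) > 1:
            raise ValueError("trait-module correlation rho must satisfy |rho| <= 1")
        f = truth.factors[module].to_numpy()
        if abs(rho) == 1:
            table[trait] = np.sign(rho) * f
        else:
            table[trait] = rho * f + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    for t in range(n_null_traits):
        table[f"null{t + 1}"] = rng.standard_normal(n)
    traits = pd.DataFrame(table, index=truth.factors.index)
    traits.index.name = "sample_id"
    traits.columns.name = "trait"
    if missing_rate > 0:
        mask = rng.random(traits.shape) < missing_rate
        traits = traits.mask(mask)
    truth.trait_links = dict(links)
    return traits


def symmetric_target(n_samples: int = DEFAULT_N_SAMPLES, seed: int = 0,
                     name: str = "MVD") -> pd.Series:
    """An exactly zero-centered, symmetric, unit-variance target trait.

    Half the samples are drawn uniform on (0, sqrt(3)) and mirrored, so
    the empirical distribution is symmetric by construction: any even
    function of the target has exactly zero sample covariance with it.
    Uniform spread (the convention of functional-relationship
    benchmarks) keeps both arms of a planted parabola populated instead
    of clustering mass near zero.
    """
    if n_samples % 2:
        raise ValueError("symmetric target needs an even sample count")
    rng = np.random.default_rng(seed)
    half = rng.uniform(0.0, np.sqrt(3.0), n_samples // 2)
    values = np.concatenate([half, -half])
    return pd.Series(values, index=_sample_ids(n_samples), name=name)


def generate_peptides(target: pd.Series,
                      n_linear: int = 5,
                      n_parabola: int = 5,
                      n_sinusoid: int = 0,
                      n_noise: int = 190,
                      noise_sd: float = 0.3,
                      seed: int = 0,
                      omega: float = 4.0) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Plant functional relationships to a trait in a peptide-style matrix.

    Each planted feature is a deterministic function of the target —
    linear (a*t), parabolic (a*(t - mean)^2, Pearson-invisible when the
    target is symmetric around its mean), or sinusoidal (a*sin(omega*t))
    — standardized to unit variance and perturbed by N(0, noise_sd^2)
    noise, so ``noise_sd`` is a signal-relative noise level.  The
    remaining features are independent standard normal.
    """
    t = target.to_numpy(dtype=float)
    if len(t) < 8:
        raise ValueError("target needs at least 8 samples")
    rng = np.random.default_rng(seed)

    def _standardize(signal: np.ndarray) -> np.ndarray:
        sd = signal.std(ddof=1)
        if sd == 0:
            raise ValueError("degenerate planted signal (constant)")
        return (signal - signal.mean()) / sd

    signals: list[tuple[str, np.ndarray]] = []
    for _ in range(n_linear):
        signals.append(("linear", _standardize(t)))
    for _ in range(n_parabola):
        signals.append(("parabola", _standardize((t - t.mean()) ** 2)))
    for _ in range(n_sinusoid):
        signals.append(("sinusoid", _standardize(np.sin(omega * t))))

    columns, classes = [], {}
    data = np.empty((len(t), len(signals) + n_noise))
    for i, (kind, signal) in enumerate(signals):
        data[:, i] = signal + rng.normal(0.0, noise_sd, size=len(t))
        name = f"P{i + 1:04d}"
        columns.append(name)
        classes[name] = kind
    for i in range(n_noise):
        j = len(signals) + i
        data[:, j] = rng.standard_normal(len(t))
        name = f"P{j + 1:04d}"
        columns.append(name)
        classes[name] = NOISE_LABEL

    matrix = pd.DataFrame(data, index=target.index, columns=columns)
    matrix.index.name = "sample_id"
    matrix.columns.name = "feature_id"
    truth = SyntheticTruth(
        membership=pd.Series(classes, name="class"),
        peptide_classes=pd.Series(classes, name="class"),
        noise_sd=float(noise_sd),
        seed=int(seed),
    )
    return matrix, truth
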