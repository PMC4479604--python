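"""Sampling of synapse configurations from measured size distributions.

The size of a cortical synaptic junction is summarized by the side length
``Ls`` of a square PSD whose area equals the measured synaptic apposition
surface (SAS).  Three-dimensional EM reconstructions show that the Feret
diameter ``D_F`` of synaptic junctions in rat somatosensory cortex layer III
is log-normally distributed; ``Ls = sqrt(SAS) = k * D_F`` with a measured
shape factor ``k``, so ``ln Ls`` inherits the normal law of ``ln D_F``
shifted by ``ln k``.

A synapse *configuration* is one joint draw of (Ls, La, [AMPAr], [GluT]):
the PSD side length, the side length of the total pre/post membrane
apposition, and the surface densities of AMPA receptors and glutamate
transporters.  These four values, plus a per-configuration seed, fully
determine a model synapse.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SizeDistribution",
    "SynapseConfig",
    "derive_ls_lognormal",
    "compute_nampa",
    "sample_configs",
    "configs_to_frame",
    "frame_to_configs",
    "write_population",
    "read_population",
    "DF_LOGNORMAL_MU",
    "DF_LOGNORMAL_SIGMA",
    "SAS_SHAPE_FACTOR",
    "LS_RANGE_NM",
    "AMPAR_DENSITY_RANGE",
    "GLUT_DENSITY_RANGE",
    "LA_FACTOR_RANGE",
]

#: log-normal parameters of the Feret diameter D_F (ln nm), layer III rat
#: somatosensory cortex (1695 reconstructed junctions).
DF_LOGNORMAL_MU = 5.828
DF_LOGNORMAL_SIGMA = 0.446

#: proportionality between sqrt(SAS) and D_F measured on 250 junctions.
SAS_SHAPE_FACTOR = 0.624

#: realized range of PSD side lengths (nm).
LS_RANGE_NM = (60.0, 825.0)

#: AMPA receptor surface density range (molecules / um^2).
AMPAR_DENSITY_RANGE = (500.0, 3000.0)

#: glutamate transporter surface density range (molecules / um^2).
GLUT_DENSITY_RANGE = (7000.0, 12000.0)

#: La is uniform between 1 and 2 times Ls.
LA_FACTOR_RANGE = (1.0, 2.0)


@dataclass(frozen=True)
class SizeDistribution:
    """Log-normal law of the PSD side length Ls, derived from D_F.

    Parameters are on the natural-log scale, lengths in nm.
    """

    mu_DF: float
    sigma_DF: float
    k: float
    mu_Ls: float
    sigma_Ls: float
    range_Ls: tuple[float, float] = LS_RANGE_NM

    def __post_init__(self) -> None:
        if self.sigma_DF <= 0:
            raise ValueError("sigma_DF must be positive")
        if not (0 < self.k <= 1):
            raise ValueError("k must lie in (0, 1]")
        if not math.isclose(self.mu_Ls, self.mu_DF + math.log(self.k), rel_tol=1e-9):
            raise ValueError("mu_Ls must equal mu_DF + ln(k)")
        if self.range_Ls[0] >= self.range_Ls[1]:
            raise ValueError("empty Ls range")

    @property
    def median_Ls(self) -> float:
        """Median of the (untruncated) Ls distribution, nm."""
        return math.exp(self.mu_Ls)


def derive_ls_lognormal(
    mu_DF: float = DF_LOGNORMAL_MU,
    sigma_DF: float = DF_LOGNORMAL_SIGMA,
    k: float = SAS_SHAPE_FACTOR,
    range_Ls: tuple[float, float] = LS_RANGE_NM,
) -> SizeDistribution:
    """Translate the log-normal law of D_F into the law of Ls = k * D_F.

    Multiplying a log-normal variate by ``k`` shifts its log-scale location
    by ``ln k`` and leaves the log-scale sd unchanged.
    """
    if sigma_DF <= 0:
        raise ValueError("sigma_DF must be positive")
    if k <= 0:
        raise ValueError("k must be positive")
    return SizeDistribution(
        mu_DF=mu_DF,
        sigma_DF=sigma_DF,
        k=k,
        mu_Ls=mu_DF + math.log(k),
        sigma_Ls=sigma_DF,
        range_Ls=range_Ls,
    )


def compute_nampa(ampar_density: float, Ls: float) -> int:
    """Number of AMPA receptors: round(density * Ls^2 * 1e-6), at least 1.

    ``ampar_density`` in molecules/um^2, ``Ls`` in nm.  Rounding is
    half-away-from-zero; a synapse always carries at least one receptor.
    """
    if ampar_density <= 0 or Ls <= 0:
        raise ValueError("ampar_density and Ls must be positive")
    n = int(math.floor(ampar_density * Ls * Ls * 1e-6 + 0.5))
    return max(n, 1)


@dataclass
class SynapseConfig:
    """One sampled synapse: geometry side lengths, densities and seed."""

    id: str
    Ls: float  # PSD side length, nm
    La: float  # apposition side length, nm
    ampar_density: float  # receptors / um^2
    glut_density: float  # transporters / um^2
    seed: int
    T: float = 35.0  # temperature, degrees C

    def __post_init__(self) -> None:
        if not (self.Ls <= self.La <= 2.0 * self.Ls + 1e-9):
            raise ValueError(f"La must lie in [Ls, 2 Ls]; got Ls={self.Ls}, La={self.La}")
        if self.Ls <= 0:
            raise ValueError("Ls must be positive")
        if self.ampar_density <= 0 or self.glut_density < 0:
            raise ValueError("densities must be positive (GluT may be 0 in tests)")

    @property
    def As(self) -> float:
        """PSD area, nm^2."""
        return self.Ls * self.Ls

    @property
    def nAMPA(self) -> int:
        return compute_nampa(self.ampar_density, self.Ls)


def _config_seed(root_seed: int, index: int) -> int:
    """Counter-based per-configuration seed, reproducible in isolation."""
    ss = np.random.SeedSequence([int(root_seed), int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _truncated_lognormal(
    rng: np.random.Generator, n: int, mu: float, sigma: float, lo: float, hi: float
) -> np.ndarray:
    """Rejection sampling of a log-normal restricted to [lo, hi]."""
    from scipy import stats

    mass = stats.lognorm.cdf(hi, s=sigma, scale=math.exp(mu)) - stats.lognorm.cdf(
        lo, s=sigma, scale=math.exp(mu)
    )
    if mass <= 0:
        raise ValueError("empty truncation interval for Ls")
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mean=mu, sigma=sigma, size=max(n - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def sample_configs(
    n: int,
    dist: SizeDistribution | None = None,
    *,
    ampar_range: tuple[float, float] = AMPAR_DENSITY_RANGE,
    glut_range: tuple[float, float] = GLUT_DENSITY_RANGE,
    la_factor_range: tuple[float, float] = LA_FACTOR_RANGE,
    seed: int = 0,
    truncate: bool = True,
    temperature: float = 35.0,
    id_prefix: str = "syn",
) -> list[SynapseConfig]:
    """Sample ``n`` synapse configurations.

    Ls is log-normal (truncated to ``dist.range_Ls`` by rejection when
    ``truncate`` is set); La = Ls * U(1, 2); the two densities are
    independent uniforms.  Deterministic given ``seed``; each configuration
    additionally receives its own derived seed so that any single synapse
    can be re-simulated in isolation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if dist is None:
        dist = derive_ls_lognormal()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0FF]))
    if truncate:
        ls = _truncated_lognormal(
            rng, n, dist.mu_Ls, dist.sigma_Ls, dist.range_Ls[0], dist.range_Ls[1]
        )
    else:
        ls = rng.lognormal(mean=dist.mu_Ls, sigma=dist.sigma_Ls, size=n)
    la_factor = rng.uniform(*la_factor_range, size=n)
    ampar = rng.uniform(*ampar_range, size=n)
    glut = rng.uniform(*glut_range, size=n)
    configs = []
    for i in range(n):
        configs.append(
            SynapseConfig(
                id=f"{id_prefix}{i:04d}",
                Ls=float(ls[i]),
                La=float(ls[i] * la_factor[i]),
                ampar_density=float(ampar[i]),
                glut_density=float(glut[i]),
                seed=_config_seed(seed, i),
                T=temperature,
            )
        )
    return configs


def configs_to_frame(configs: Sequence[SynapseConfig]) -> pd.DataFrame:
    """One row per configuration, including the derived As and nAMPA."""
    rows = []
    for c in configs:
        d = dataclasses.asdict(c)
        d["As"] = c.As
        d["nAMPA"] = c.nAMPA
        rows.append(d)
    return pd.DataFrame(rows)


def frame_to_configs(df: pd.DataFrame) -> list[SynapseConfig]:
    return [
        SynapseConfig(
            id=str(r.id),
            Ls=float(r.Ls),
            La=float(r.La),
            ampar_density=float(r.ampar_density),
            glut_density=float(r.glut_density),
            seed=int(r.seed),
            T=float(r.T),
        )
        for r in df.itertuples(index=False)
    ]


def write_population(
    configs: Sequence[SynapseConfig],
    csv_path: str | Path,
    manifest_path: str | Path | None = None,
    *,
    dist: SizeDistribution | None = None,
    root_seed: int | None = None,
) -> None:
    """Persist a sampled population as CSV plus a JSON manifest."""
    csv_path = Path(csv_path)
    configs_to_frame(configs).to_csv(csv_path, index=False)
    if manifest_path is not None:
        if dist is None:
            dist = derive_ls_lognormal()
        manifest = {
            "n_configs": len(configs),
            "root_seed": root_seed,
            "size_distribution": dataclasses.asdict(dist),
            "ampar_density_range": list(AMPAR_DENSITY_RANGE),
            "glut_density_range": list(GLUT_DENSITY_RANGE),
            "la_factor_range": list(LA_FACTOR_RANGE),
            "columns": list(configs_to_frame(configs[:1]).columns),
        }
        Path(manifest_path).write_text(json.dumps(manifest, indent=2))


def read_population(csv_path: str | Path) -> list[SynapseConfig]:
    return frame_to_configs(pd.read_csv(csv_path))
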