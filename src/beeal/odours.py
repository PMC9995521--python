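"""Odorants as receptor-affinity profiles.

An odorant is characterised by how strongly it binds to each of the
``n_glo`` olfactory receptor types.  Binding rate constants ``k1`` follow a
Gaussian profile over receptor-type index — peak sensitivity ``10**eta``,
width ``sigma`` (in receptor-index units) — which is then scrambled by a
random permutation so that chemically similar receptors are not neighbours
in glomerular space.  The two-stage transduction kinetics additionally need
an activation rate ``k2`` and the unbinding/deactivation rates ``k_minus1``
and ``k_minus2`` (0.025 kHz for every odour and receptor type by default).

Random odour libraries are sampled from truncated normal distributions:
``eta ~ N(1.5, 0.5^2)`` truncated to [0, 4], ``sigma ~ N(3, 0.5^2)``
truncated to >= 1.5, and ``k2 ~ N(0.02, 0.02^2)`` truncated to
[0.0028, 0.2] kHz.  Two designated odours, "IAA" (narrow, low sensitivity,
fast activation) and "Geosmin" (broad, high sensitivity, slow activation),
are constructed with their peaks a fixed distance apart and scrambled with
one shared permutation so that their receptor overlap is controlled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "OdourProfile",
    "OdourLibrary",
    "gaussian_k1_profile",
    "sample_random_odour",
    "make_designated_pair",
    "GEOSMIN_K2_PRESETS",
]

#: Default unbinding / deactivation rate, kHz (identical for all odours).
DEFAULT_K_OFF = 0.025

#: Named presets for the Geosmin activation rate k2 (kHz).  The slower
#: "methods" value is used for concentration sweeps and PN maps; the faster
#: "results" value (k2 ratio ~1:3 against IAA's 0.1) is the one used for the
#: ORN mixture / EAG-proxy experiment.
GEOSMIN_K2_PRESETS = {"methods": 0.003, "results": 0.03}


@dataclass(frozen=True)
class OdourProfile:
    """Receptor-affinity profile and transduction kinetics of one odorant.

    Parameters
    ----------
    name : str
        Label ("IAA", "Geosmin", "odour_017", ...).
    k1 : ndarray, shape (n_glo,)
        Binding rate constants per receptor type, kHz per unit
        concentration, already scrambled by `permutation`.
    k2 : float
        Activation rate constant, kHz (same for all receptor types).
    k_minus1, k_minus2 : float
        Unbinding and deactivation rates, kHz.
    eta : float
        log10 peak sensitivity; ``max(k1) == 10**eta`` up to the index
        discretisation of the Gaussian.
    sigma : float
        Profile width in receptor-type index units.
    center : int
        Peak receptor index of the unscrambled profile.
    permutation : ndarray of int, shape (n_glo,)
        Bijection applied to the unscrambled profile:
        ``k1[j] = unscrambled[permutation[j]]``.
    """

    name: str
    k1: np.ndarray
    k2: float
    eta: float
    sigma: float
    center: int
    permutation: np.ndarray
    k_minus1: float = DEFAULT_K_OFF
    k_minus2: float = DEFAULT_K_OFF

    def __post_init__(self) -> None:
        k1 = np.asarray(self.k1, dtype=float)
        perm = np.asarray(self.permutation, dtype=np.intp)
        object.__setattr__(self, "k1", k1)
        object.__setattr__(self, "permutation", perm)
        if k1.ndim != 1:
            raise ValueError("k1 must be a 1-D vector over receptor types")
        if np.any(k1 < 0):
            raise ValueError("binding rates k1 must be non-negative")
        if perm.shape != k1.shape or not np.array_equal(np.sort(perm), np.arange(k1.size)):
            raise ValueError("permutation must be a bijection of receptor indices")

    @property
    def n_glo(self) -> int:
        return self.k1.size

    def unscrambled_k1(self) -> np.ndarray:
        """Invert the permutation, recovering the unimodal Gaussian profile."""
        out = np.empty_like(self.k1)
        out[self.permutation] = self.k1
        return out

    def with_k2(self, k2: float, suffix: str | None = None) -> "OdourProfile":
        name = self.name if suffix is None else f"{self.name}{suffix}"
        return replace(self, k2=float(k2), name=name)


def gaussian_k1_profile(
    eta: float,
    sigma: float,
    center: int,
    n_glo: int,
    *,
    one_sided: bool = False,
) -> np.ndarray:
    """Gaussian binding-rate profile over receptor-type index.

    ``k1[j] = 10**eta * exp(-d(j)**2 / (2 sigma**2))`` with
    ``d(j) = j - center`` (index offset; no circular wrap — the profile is
    truncated at the index bounds).  With ``one_sided=True`` the alternative
    one-sided dialect ``d(j) = j + 1`` is used instead (peak adjacent to
    index 0, monotone decay); `center` is ignored in that case.

    Parameters are dimensionless except the returned rates, which are in
    kHz per unit concentration.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if n_glo < 1:
        raise ValueError("n_glo must be >= 1")
    j = np.arange(n_glo, dtype=float)
    if one_sided:
        d = j + 1.0
    else:
        if not 0 <= center < n_glo:
            raise ValueError(f"center {center} outside receptor index range 0..{n_glo - 1}")
        d = j - center
    return 10.0**eta * np.exp(-(d**2) / (2.0 * sigma**2))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = -np.inf, hi: float = np.inf) -> float:
    # rejection sampling from the parent normal: simple and exact
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)


def sample_random_odour(
    rng: np.random.Generator,
    n_glo: int,
    *,
    name: str = "odour",
    perm_rng: np.random.Generator | None = None,
) -> OdourProfile:
    """Draw one odorant from the random-odour distributions.

    `perm_rng`, if given, is a separate stream used only for the scrambling
    permutation, so that varying the parameter stream leaves permutations
    unchanged (and vice versa).
    """
    eta = _truncated_normal(rng, 1.5, 0.5, 0.0, 4.0)
    sigma = _truncated_normal(rng, 3.0, 0.5, 1.5)
    k2 = _truncated_normal(rng, 0.02, 0.02, 0.0028, 0.2)
    center = n_glo // 2
    base = gaussian_k1_profile(eta, sigma, center, n_glo)
    perm = (perm_rng if perm_rng is not None else rng).permutation(n_glo)
    return OdourProfile(
        name=name, k1=base[perm], k2=k2, eta=eta, sigma=sigma,
        center=center, permutation=np.asarray(perm),
    )


def make_designated_pair(
    n_glo: int,
    peak_distance: int = 30,
    rng: np.random.Generator | None = None,
    *,
    geosmin_k2: float | str = "methods",
) -> tuple[OdourProfile, OdourProfile]:
    """Construct the designated ("IAA", "Geosmin") odour pair.

    "IAA" is narrow (sigma=3) with low peak sensitivity (eta=0.8) but a fast
    activation rate (k2=0.1 kHz).  "Geosmin" is broad (sigma=10) with very
    high sensitivity (eta=4.4) and slow-to-moderate activation
    (`geosmin_k2`: a value in kHz or one of the preset names
    ``"methods"`` -> 0.003, ``"results"`` -> 0.03).  Their unscrambled peaks
    sit `peak_distance` receptor types apart and both profiles are scrambled
    with one shared permutation, fixing their receptor overlap.
    """
    if not 0 <= peak_distance < n_glo:
        raise ValueError(f"peak_distance {peak_distance} must be < n_glo ({n_glo})")
    if isinstance(geosmin_k2, str):
        try:
            geo_k2 = GEOSMIN_K2_PRESETS[geosmin_k2]
        except KeyError:
            raise ValueError(
                f"unknown geosmin_k2 preset {geosmin_k2!r}; "
                f"choose from {sorted(GEOSMIN_K2_PRESETS)}"
            ) from None
    else:
        geo_k2 = float(geosmin_k2)
    rng = np.random.default_rng(rng)
    c_iaa = (n_glo - peak_distance) // 2
    c_geo = c_iaa + peak_distance
    perm = rng.permutation(n_glo)
    iaa_base = gaussian_k1_profile(0.8, 3.0, c_iaa, n_glo)
    geo_base = gaussian_k1_profile(4.4, 10.0, c_geo, n_glo)
    iaa = OdourProfile(name="IAA", k1=iaa_base[perm], k2=0.1, eta=0.8,
                       sigma=3.0, center=c_iaa, permutation=perm)
    geo = OdourProfile(name="Geosmin", k1=geo_base[perm], k2=geo_k2, eta=4.4,
                       sigma=10.0, center=c_geo, permutation=perm)
    return iaa, geo


@dataclass
class OdourLibrary:
    """Ordered collection of odour profiles with its generating seed."""

    odours: list[OdourProfile]
    rng_seed: int | None = None
    n_random: int = 0

    def __len__(self) -> int:
        return len(self.odours)

    def __iter__(self):
        return iter(self.odours)

    def __getitem__(self, key: int | str) -> OdourProfile:
        if isinstance(key, str):
            for od in self.odours:
                if od.name == key:
                    return od
            raise KeyError(f"no odour named {key!r} in library")
        return self.odours[key]

    @property
    def names(self) -> list[str]:
        return [od.name for od in self.odours]

    @classmethod
    def generate(
        cls,
        n_glo: int = 160,
        n_random: int = 98,
        seed: int | None = None,
        *,
        include_designated: bool = True,
        peak_distance: int = 30,
        geosmin_k2: float | str = "methods",
    ) -> "OdourLibrary":
        """Generate the default library: `n_random` random odours plus the
        designated pair (default 98 + 2 = 100 odours).

        Two independent child streams of `seed` drive (i) odour parameters
        and (ii) permutations, so each can be varied in isolation.
        """
        root = np.random.default_rng(seed)
        param_rng, perm_rng = root.spawn(2)
        odours = [
            sample_random_odour(param_rng, n_glo, name=f"odour_{i:03d}",
                                perm_rng=perm_rng)
            for i in range(n_random)
        ]
        if include_designated:
            iaa, geo = make_designated_pair(
                n_glo, peak_distance, perm_rng, geosmin_k2=geosmin_k2)
            odours += [iaa, geo]
        return cls(odours=odours, rng_seed=seed, n_random=n_random)

    # -- plain-text serialisation ------------------------------------------

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(parameter table, k1 matrix) — one row per odour."""
        params = pd.DataFrame(
            {
                "name": self.names,
                "eta": [od.eta for od in self.odours],
                "sigma": [od.sigma for od in self.odours],
                "k2": [od.k2 for od in self.odours],
                "k_minus1": [od.k_minus1 for od in self.odours],
                "k_minus2": [od.k_minus2 for od in self.odours],
                "center": [od.center for od in self.odours],
                "seed": self.rng_seed,
            }
        )
        k1 = pd.DataFrame(
            np.stack([od.k1 for od in self.odours]),
            index=self.names,
            columns=[f"OR{j:03d}" for j in range(self.odours[0].n_glo)],
        )
        return params, k1

    def save(self, params_path, k1_path) -> None:
        params, k1 = self.to_frames()
        params.to_csv(params_path, index=False)
        k1.to_csv(k1_path)
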