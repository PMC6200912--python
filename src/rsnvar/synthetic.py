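"""Synthetic parcellated BOLD sessions with known ground truth.

Every downstream stage is exercised on data from this module: runs are
mixtures of band-limited (0.01-0.05 Hz) network sources and
high-frequency (>0.1 Hz) artifact sources, mixed into regions through
ground-truth spatial maps, plus white noise scaled by the requested
SNR.  PET maps are drawn with a dial-in correlation to the ground-truth
maximum graph-strength map, and motion traces with configurable drift
and jitter.  All randomness flows from explicit seeds through
``numpy.random.default_rng``; fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ConfigurationError
from .graph import network_strength_map
from .motion import MotionTrace
from .parcellation import ParcellatedSeries, PetRoiMap, RoiAtlas, RSN_NAMES

#: Neuronal source pass-band (Hz).
NEURONAL_BAND = (0.01, 0.05)
#: Artifact sources live above this frequency (Hz).
ARTIFACT_HIGHPASS = 0.1
_FILTER_ORDER = 4


@dataclass
class SimulationConfig:
    """Knobs of the synthetic session generator.

    ``snr`` is the amplitude ratio of each source to the additive white
    noise; ``leakage`` puts reduced-amplitude source weight on a
    fraction of non-member regions so template mismatch can be dialed
    in.  ``np.inf`` is a valid snr (noiseless).
    """

    n_regions: int = 60
    n_networks: int = 9
    regions_per_network: int = 5
    run_length: int = 480
    tr: float = 1.0
    n_artifact_sources: int = 3
    snr: float = 3.0
    pet_coupling: float = 0.5
    leakage: float = 0.0
    leakage_amplitude: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_networks * self.regions_per_network > self.n_regions:
            raise ConfigurationError(
                f"{self.n_networks} networks x {self.regions_per_network} "
                f"regions exceed the {self.n_regions} available regions")
        if self.run_length < 64:
            raise ConfigurationError("run_length must be at least 64")
        if self.tr <= 0:
            raise ConfigurationError("tr must be positive")
        if not 0.0 <= self.pet_coupling <= 1.0:
            raise ConfigurationError("pet_coupling must lie in [0, 1]")
        if not 0.0 <= self.leakage <= 1.0:
            raise ConfigurationError("leakage must lie in [0, 1]")
        if self.snr <= 0:
            raise ConfigurationError("snr must be positive")
        nyquist = 0.5 / self.tr
        if NEURONAL_BAND[1] >= nyquist or ARTIFACT_HIGHPASS >= nyquist:
            raise ConfigurationError(
                f"band edges incompatible with tr={self.tr} "
                f"(Nyquist {nyquist} Hz)")


@dataclass
class GroundTruth:
    """What the generator planted, in the shape the pipeline recovers."""

    network_names: list[str]
    network_membership: dict[str, frozenset[int]]
    true_zmaps: np.ndarray                    # (sources, N) mixing maps
    source_timecourses: np.ndarray | None     # (sources, T), None if unmixed
    neuronal: list[bool] = field(default_factory=list)
    pet_map: np.ndarray | None = None
    motion: MotionTrace | None = None
    _max_gs: np.ndarray | None = None

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    def max_gs_map(self) -> np.ndarray:
        """Elementwise max of the per-network ground-truth strengths.

        Exploits that edges incident to a zero-weight region are exactly
        zero (w_ij = 0 whenever z_i = 0), so each network's strength map
        is computed on its nonzero support only; identical to the full
        N x N computation.
        """
        if self._max_gs is None:
            maps = []
            for i in range(self.n_networks):
                z = self.true_zmaps[i]
                support = np.flatnonzero(z)
                s = np.zeros(z.size)
                if support.size >= 2:
                    s[support] = network_strength_map(z[support]).s
                maps.append(s)
            self._max_gs = np.max(np.vstack(maps), axis=0)
        return self._max_gs


def _network_names(n_networks: int) -> list[str]:
    names = list(RSN_NAMES[:n_networks])
    names += [f"net{i + 1}" for i in range(len(names), n_networks)]
    return names


def make_atlas(config: SimulationConfig,
               with_image: bool = False) -> RoiAtlas:
    """Atlas of N regions with disjoint network templates.

    Region ids are 1..N; the first ``n_networks * regions_per_network``
    regions are chunked into the templates.  ``with_image`` materializes
    a small 3D label image (two voxels per region) for voxel-level I/O
    tests.
    """
    n = config.n_regions
    ids = np.arange(1, n + 1)
    names = _network_names(config.n_networks)
    templates = {
        name: frozenset(
            ids[k * config.regions_per_network:
                (k + 1) * config.regions_per_network].tolist())
        for k, name in enumerate(names)
    }
    label_image = None
    if with_image:
        label_image = np.repeat(ids, 2).reshape(n, 2, 1).astype(int)
    return RoiAtlas(
        region_ids=ids,
        region_names={int(i): f"region_{i}" for i in ids},
        rsn_templates=templates,
        label_image=label_image,
        affine=np.eye(4) if with_image else None,
    )


def _bandlimited_noise(rng: np.random.Generator, n_sources: int, T: int,
                       tr: float, band: tuple[float, float] | None,
                       highpass: float | None = None) -> np.ndarray:
    """Zero-phase filtered white noise, standardized per source."""
    fs = 1.0 / tr
    x = rng.standard_normal((n_sources, T))
    if band is not None:
        sos = signal.butter(_FILTER_ORDER, band, btype="bandpass",
                            fs=fs, output="sos")
    else:
        sos = signal.butter(_FILTER_ORDER, highpass, btype="highpass",
                            fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=1)
    y -= y.mean(axis=1, keepdims=True)
    sd = y.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def make_ground_truth(atlas: RoiAtlas, config: SimulationConfig,
                      rng: np.random.Generator) -> GroundTruth:
    """Plant spatial maps: network sources plus artifact sources.

    Member regions of network k get unit-scale positive weight (with
    mild amplitude variation); a ``leakage`` fraction of non-member
    regions gets reduced weight.  Artifact maps load diffusely on a
    random third of the regions.
    """
    names = _network_names(config.n_networks)
    n = atlas.n_regions
    n_sources = config.n_networks + config.n_artifact_sources
    zmaps = np.zeros((n_sources, n))
    membership: dict[str, frozenset[int]] = {}
    for k, name in enumerate(names):
        members = atlas.rsn_templates[name]
        membership[name] = members
        idx = atlas.member_indices(name)
        zmaps[k, idx] = rng.uniform(0.8, 1.2, size=idx.size)
        if config.leakage > 0:
            outside = np.setdiff1d(np.arange(n), idx)
            n_leak = int(round(config.leakage * outside.size))
            if n_leak:
                leak_idx = rng.choice(outside, size=n_leak, replace=False)
                zmaps[k, leak_idx] = config.leakage_amplitude * \
                    rng.uniform(0.8, 1.2, size=n_leak)
    for a in range(config.n_artifact_sources):
        k = config.n_networks + a
        n_load = max(2, n // 3)
        idx = rng.choice(n, size=n_load, replace=False)
        zmaps[k, idx] = rng.uniform(0.5, 1.5, size=n_load)
    neuronal = [True] * config.n_networks + \
        [False] * config.n_artifact_sources
    return GroundTruth(network_names=names, network_membership=membership,
                       true_zmaps=zmaps, source_timecourses=None,
                       neuronal=neuronal)


def simulate_run(atlas: RoiAtlas, config: SimulationConfig,
                 seed: int) -> tuple[ParcellatedSeries, GroundTruth]:
    """One synthetic BOLD run: sources mixed through planted maps.

    series = networks + artifacts + white noise / snr, all per-source
    amplitudes at unit scale.  Bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    truth = make_ground_truth(atlas, config, rng)
    T = config.run_length
    net_sources = _bandlimited_noise(rng, config.n_networks, T, config.tr,
                                     NEURONAL_BAND)
    if config.n_artifact_sources:
        art_sources = _bandlimited_noise(rng, config.n_artifact_sources, T,
                                         config.tr, None,
                                         highpass=ARTIFACT_HIGHPASS)
        sources = np.vstack([net_sources, art_sources])
    else:
        sources = net_sources
    truth.source_timecourses = sources
    data = sources.T @ truth.true_zmaps
    noise_sd = 0.0 if math.isinf(config.snr) else 1.0 / config.snr
    if noise_sd:
        data = data + noise_sd * rng.standard_normal(data.shape)
    series = ParcellatedSeries(data=data, tr=config.tr, run_label="run")
    return series, truth


def simulate_pet(truth: GroundTruth, coupling: float,
                 seed: int) -> PetRoiMap:
    """PET map with expected Pearson correlation ``coupling`` to the
    ground-truth max-GS map.

    pet = coupling * z(max GS) + sqrt(1 - coupling^2) * z(noise).
    """
    if not 0.0 <= coupling <= 1.0:
        raise ConfigurationError("coupling must lie in [0, 1]")
    gs = truth.max_gs_map()
    gs_z = (gs - gs.mean()) / gs.std()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(gs.size)
    noise_z = (noise - noise.mean()) / noise.std()
    pet = coupling * gs_z + math.sqrt(1.0 - coupling ** 2) * noise_z
    truth.pet_map = pet
    return PetRoiMap(values=pet)


def simulate_motion(config: SimulationConfig, seed: int,
                    drift_mm_per_tr: float = 0.0,
                    jitter_sd: float = 0.0) -> MotionTrace:
    """T x 6 motion table: linear drift on TraX plus i.i.d. jitter."""
    T = config.run_length
    rng = np.random.default_rng(seed)
    params = np.zeros((T, 6))
    params[:, 0] = drift_mm_per_tr * np.arange(T)
    if jitter_sd > 0:
        params += jitter_sd * rng.standard_normal((T, 6))
    return MotionTrace(params=params, tr=config.tr)
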