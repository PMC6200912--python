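"""Spatial ICA decomposition, component fingerprints, and network
assignment.

A run is decomposed into ``k`` spatial components (default 30).  Each
component is an N-vector of region z-values paired with a T-vector time
course.  Components are characterized by an 11-dimensional fingerprint
(4 spatial + 7 temporal features), classified neuronal vs non-neuronal
by their spectral content, and matched to binary network templates by a
goodness-of-fit score (mean z inside the template minus mean z outside),
with a greedy exclusive assignment across all networks simultaneously.

Conventions fixed here because ICA leaves them free:

* z-maps are standardized to mean 0 / sd 1 over regions;
* the component sign is flipped so the spatial skewness is >= 0;
* components are ordered by explained variance of their time courses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal, stats
from sklearn.decomposition import FastICA

from .errors import ConfigurationError, ValidationError
from .parcellation import ParcellatedSeries, RoiAtlas

#: The five fingerprint frequency bands (Hz).
FINGERPRINT_BANDS = (
    (0.0, 0.008),
    (0.008, 0.02),
    (0.02, 0.05),
    (0.05, 0.1),
    (0.1, 0.25),
)

#: Band regarded as neuronal BOLD fluctuation (Hz).
NEURONAL_BAND = (0.01, 0.05)
#: High-frequency band typical of physiological artifact (Hz).
ARTIFACT_BAND = (0.1, 0.25)

HISTOGRAM_BINS = 32
DEFAULT_K = 30


@dataclass
class ComponentSet:
    """K spatial z-maps (K x N) with paired time courses (K x T)."""

    zmaps: np.ndarray
    timecourses: np.ndarray
    tr: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.zmaps = np.asarray(self.zmaps, dtype=float)
        self.timecourses = np.asarray(self.timecourses, dtype=float)
        if self.zmaps.ndim != 2 or self.timecourses.ndim != 2:
            raise ValidationError("zmaps and timecourses must be 2D")
        if self.zmaps.shape[0] != self.timecourses.shape[0]:
            raise ValidationError("zmaps/timecourses component count mismatch")
        if self.tr <= 0:
            raise ValidationError("tr must be positive")

    @property
    def k(self) -> int:
        return int(self.zmaps.shape[0])

    @property
    def n_regions(self) -> int:
        return int(self.zmaps.shape[1])


@dataclass
class Fingerprint:
    """11-D spatial/temporal component descriptor.

    ``band_power_1..5`` are fractions of total periodogram power in the
    five bands 0-0.008, 0.008-0.02, 0.02-0.05, 0.05-0.1, 0.1-0.25 Hz.
    ``neuronal_band_power`` (0.01-0.05 Hz) and ``artifact_band_power``
    are auxiliary fractions used by the classifier, not part of the 11-D
    space.
    """

    clustering_degree: float
    spatial_skewness: float
    spatial_kurtosis: float
    spatial_entropy: float
    one_lag_autocorr: float
    temporal_entropy: float
    band_power_1: float
    band_power_2: float
    band_power_3: float
    band_power_4: float
    band_power_5: float
    neuronal_band_power: float = 0.0
    artifact_band_power: float = 0.0
    degenerate: bool = False

    def as_vector(self) -> np.ndarray:
        """The 11 features in documented order."""
        return np.array([
            self.clustering_degree, self.spatial_skewness,
            self.spatial_kurtosis, self.spatial_entropy,
            self.one_lag_autocorr, self.temporal_entropy,
            self.band_power_1, self.band_power_2, self.band_power_3,
            self.band_power_4, self.band_power_5,
        ])

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class NetworkAssignment:
    """Exclusive network -> component mapping with goodness-of-fit."""

    assigned: dict[str, tuple[int, float, bool]] = field(default_factory=dict)
    unassigned: list[str] = field(default_factory=list)

    def component_of(self, network: str) -> int | None:
        entry = self.assigned.get(network)
        return None if entry is None else entry[0]

    def is_neuronal(self, network: str) -> bool:
        entry = self.assigned.get(network)
        return bool(entry is not None and entry[2])


# ---------------------------------------------------------------------------
# Decomposition


def decompose(series: ParcellatedSeries, k: int = DEFAULT_K,
              seed: int = 0, max_iter: int = 1000,
              tol: float = 1e-5) -> ComponentSet:
    """Spatial ICA of a T x N series into k components.

    The region dimension is treated as the sample axis so the recovered
    sources are spatial maps; the mixing matrix provides the paired
    time courses.  Deterministic for a fixed seed.
    """
    T, N = series.data.shape
    if k >= T:
        raise ConfigurationError(
            f"k={k} components require more than k time points (T={T})")
    if k > N:
        raise ConfigurationError(f"k={k} exceeds the region count N={N}")
    X = series.data - series.data.mean(axis=0, keepdims=True)
    ica = FastICA(n_components=k, random_state=seed, whiten="unit-variance",
                  max_iter=max_iter, tol=tol)
    with warnings.catch_warnings():
        # convergence warnings are routine at k=30 on short noisy runs
        warnings.simplefilter("ignore")
        sources = ica.fit_transform(X.T)          # (N, k) spatial maps
    timecourses = ica.mixing_.T                   # (k, T)

    zmaps = sources.T.copy()                      # (k, N)
    # standardize each map over regions, fix sign so skewness >= 0
    zmaps -= zmaps.mean(axis=1, keepdims=True)
    sd = zmaps.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    zmaps /= sd
    flip = np.where(stats.skew(zmaps, axis=1) < 0, -1.0, 1.0)
    zmaps *= flip[:, None]
    timecourses = timecourses * flip[:, None]

    # order components by time-course variance (descending), stable
    order = np.argsort(-timecourses.var(axis=1), kind="stable")
    return ComponentSet(zmaps=zmaps[order], timecourses=timecourses[order],
                        tr=series.tr, seed=seed)


# ---------------------------------------------------------------------------
# Fingerprint features


def _gini(x: np.ndarray) -> float:
    """Gini concentration of a nonnegative vector (0 = uniform)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    total = x.sum()
    if total == 0:
        return 0.0
    cum = np.cumsum(x)
    return float((n + 1 - 2 * (cum / total).sum()) / n)


def _hist_entropy(x: np.ndarray, bins: int = HISTOGRAM_BINS) -> float:
    """Shannon entropy (nats) of a fixed-bin histogram of standardized x."""
    sd = x.std()
    if sd == 0:
        return 0.0
    z = (x - x.mean()) / sd
    counts, _ = np.histogram(z, bins=bins, range=(-5, 5))
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _band_fraction(freqs: np.ndarray, power: np.ndarray,
                   band: tuple[float, float]) -> float:
    total = power.sum()
    if total == 0:
        return 0.0
    lo, hi = band
    mask = (freqs >= lo) & (freqs < hi)
    return float(power[mask].sum() / total)


def compute_fingerprint(zmap: np.ndarray, timecourse: np.ndarray,
                        tr: float) -> Fingerprint:
    """All 11 fingerprint features of one component.

    A constant time course is degenerate: band powers and autocorrelation
    are reported as 0 with the ``degenerate`` flag set.
    """
    zmap = np.asarray(zmap, dtype=float).ravel()
    timecourse = np.asarray(timecourse, dtype=float).ravel()
    if not (np.all(np.isfinite(zmap)) and np.all(np.isfinite(timecourse))):
        raise ValidationError("fingerprint inputs must be finite")
    if tr <= 0:
        raise ValidationError("tr must be positive")

    clustering = _gini(np.abs(zmap))
    sskew = float(stats.skew(zmap))
    skurt = float(stats.kurtosis(zmap, fisher=False))
    sentropy = _hist_entropy(zmap)
    tentropy = _hist_entropy(timecourse)

    degenerate = timecourse.std() == 0
    if degenerate:
        autocorr = 0.0
        bands = [0.0] * len(FINGERPRINT_BANDS)
        neuronal = artifact = 0.0
    else:
        x = timecourse - timecourse.mean()
        autocorr = float((x[:-1] * x[1:]).sum() / (x * x).sum())
        freqs, power = signal.periodogram(timecourse, fs=1.0 / tr)
        bands = [_band_fraction(freqs, power, b) for b in FINGERPRINT_BANDS]
        neuronal = _band_fraction(freqs, power, NEURONAL_BAND)
        artifact = _band_fraction(freqs, power, ARTIFACT_BAND)

    return Fingerprint(
        clustering_degree=clustering,
        spatial_skewness=sskew,
        spatial_kurtosis=skurt,
        spatial_entropy=sentropy,
        one_lag_autocorr=autocorr,
        temporal_entropy=tentropy,
        band_power_1=bands[0], band_power_2=bands[1], band_power_3=bands[2],
        band_power_4=bands[3], band_power_5=bands[4],
        neuronal_band_power=neuronal,
        artifact_band_power=artifact,
        degenerate=degenerate,
    )


def fingerprints(components: ComponentSet) -> list[Fingerprint]:
    return [compute_fingerprint(components.zmaps[i],
                                components.timecourses[i], components.tr)
            for i in range(components.k)]


# ---------------------------------------------------------------------------
# Neuronal classification


def classify_neuronal(fp: Fingerprint,
                      kurtosis_ceiling: float = 30.0) -> tuple[bool, float]:
    """Rule-based neuronal/non-neuronal call with a continuous score.

    A component is neuronal when its 0.01-0.05 Hz power fraction exceeds
    its 0.1-0.25 Hz fraction and its spatial kurtosis stays below a
    configurable ceiling.  The score is low-band minus high-band
    fraction (antisymmetric under swapping the two bands).
    """
    if fp.degenerate:
        warnings.warn("degenerate fingerprint classified non-neuronal",
                      stacklevel=2)
        return False, 0.0
    score = fp.neuronal_band_power - fp.artifact_band_power
    flag = score > 0 and fp.spatial_kurtosis < kurtosis_ceiling
    return bool(flag), float(score)


# ---------------------------------------------------------------------------
# Template matching


def goodness_of_fit(zmap: np.ndarray, template_indices: np.ndarray,
                    n_regions: int | None = None) -> float:
    """Mean z inside the template minus mean z outside it.

    ``template_indices`` are column indices into the z-map.  Linear in z
    and invariant under adding a constant.
    """
    z = np.asarray(zmap, dtype=float).ravel()
    n = z.size if n_regions is None else n_regions
    idx = np.asarray(template_indices, dtype=int)
    if idx.size == 0:
        raise ValidationError("template must be nonempty")
    if idx.size >= n:
        raise ValidationError("template must not cover every region")
    inside = np.zeros(n, dtype=bool)
    inside[idx] = True
    return float(z[inside].mean() - z[~inside].mean())


def assign_networks(components: ComponentSet, atlas: RoiAtlas,
                    neuronal_flags: list[bool] | None = None,
                    networks: list[str] | None = None) -> NetworkAssignment:
    """Greedy exclusive matching of networks to components.

    Repeatedly assigns the (network, component) pair with the globally
    largest goodness-of-fit among networks and components not yet used;
    ties break toward the lower component index, then template order.
    A network matched to a non-neuronal component is still reported,
    flagged non-neuronal.
    """
    if components.k < 1:
        raise ValidationError("need at least one component")
    names = list(networks) if networks is not None \
        else list(atlas.rsn_templates)
    if neuronal_flags is None:
        neuronal_flags = [classify_neuronal(fp)[0]
                          for fp in fingerprints(components)]

    gof = np.full((len(names), components.k), -np.inf)
    for a, net in enumerate(names):
        idx = atlas.member_indices(net)
        for c in range(components.k):
            gof[a, c] = goodness_of_fit(components.zmaps[c], idx,
                                        components.n_regions)

    assignment = NetworkAssignment()
    free_nets = list(range(len(names)))
    free_comps = list(range(components.k))
    while free_nets and free_comps:
        best = None
        for a in free_nets:
            for c in free_comps:
                key = (gof[a, c], -c, -a)  # ties: lower comp, then net order
                if best is None or key > best[0]:
                    best = (key, a, c)
        _, a, c = best
        assignment.assigned[names[a]] = (c, float(gof[a, c]),
                                         bool(neuronal_flags[c]))
        free_nets.remove(a)
        free_comps.remove(c)
    assignment.unassigned = [names[a] for a in free_nets]
    return assignment
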