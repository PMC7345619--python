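"""Seeded synthetic benchmark: library, predicted spectra, and noisy queries.

The generator emulates the statistical structure the identification
workflow assumes, at desk scale:

* **near-isobaric candidate sets** — a configurable fraction of compounds is
  placed in mass clusters whose members lie within a few ppm of each other
  (stereoisomer-like: cluster members also share an InChIKey skeleton while
  differing in the second block), so precursor searches return
  multi-candidate sets; all other masses are kept at least 40 ppm apart so
  their candidate sets are singletons;
* **energy-dependent fragmentation** — a toy fragmentation model assigns
  each compound a fixed set of fragment m/z positions (fractions of the
  precursor mass) whose intensities shift with collision energy: the
  surviving precursor peak decays with energy while low-mass fragments gain
  weight;
* **heavy-tailed data-source counts** — Zipf-distributed integer counts,
  with the true compounds' counts scaled by ``truth_ds_bias`` (>1 emulates
  well-known chemicals that metadata ranking rewards; the ``"obscure"``
  preset uses 0.2, emulating rarely-catalogued compounds for which
  metadata ranking degrades performance);
* **noisy queries** — per-peak dropout, Gaussian m/z jitter, multiplicative
  lognormal intensity noise and Poisson-count contaminant peaks applied to
  the true compound's predicted spectra, with the precursor m/z jittered at
  1 ppm (well inside the 10 ppm search window).

Everything is a pure function of (config, seed): the same configuration
yields byte-identical benchmark files.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DomainError
from .library import PROTON_MASS, CompoundRecord, SpectralLibrary, build_library
from .spectra import ENERGY_LEVELS, Peak, PredictedSpectrumSet, Spectrum, merge_spectra

#: Fraction of the precursor ion surviving at each collision energy.
PRECURSOR_SURVIVAL = {10: 0.85, 20: 0.45, 40: 0.08}

#: Exponential tilt toward low-mass fragments at each collision energy.
LOW_MASS_TILT = {10: 0.0, 20: 1.2, 40: 2.5}

#: Minimum relative separation between unrelated masses (collision-free sets).
_MIN_SEPARATION_PPM = 40.0

#: Relative spread of masses within an isobaric cluster.
_CLUSTER_SPREAD_PPM = 3.0

#: Relative precursor m/z accuracy of simulated acquisitions (1 ppm sd).
_PRECURSOR_JITTER_REL = 1e-6

_ALPHABET = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Benchmark configuration; the seed fully determines all outputs."""

    n_compounds: int = 500
    mass_range: tuple[float, float] = (100.0, 800.0)
    isobaric_group_fraction: float = 0.6
    fragments_per_compound: tuple[int, int] = (5, 15)
    ds_zipf_exponent: float = 1.6
    truth_ds_bias: float = 5.0
    dropout_p: float = 0.2
    mz_jitter_sd: float = 0.005
    intensity_cv: float = 0.2
    contaminant_rate: float = 2.0
    n_queries: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_queries < 1:
            raise ConfigError("n_compounds and n_queries must be positive")
        lo, hi = self.mass_range
        if not 0 < lo < hi:
            raise ConfigError("mass_range must satisfy 0 < min < max")
        for name in ("isobaric_group_fraction", "dropout_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.ds_zipf_exponent <= 1.0:
            raise ConfigError("ds_zipf_exponent must exceed 1")
        if self.truth_ds_bias <= 0:
            raise ConfigError("truth_ds_bias must be positive")
        f_lo, f_hi = self.fragments_per_compound
        if not 1 <= f_lo <= f_hi:
            raise ConfigError("fragments_per_compound must be a valid count range")
        if self.mz_jitter_sd < 0 or self.intensity_cv < 0 or self.contaminant_rate < 0:
            raise ConfigError("noise parameters must be non-negative")

    @classmethod
    def preset(cls, name: str, **overrides) -> "SyntheticConfig":
        """Named study conditions.

        ``"default"`` — the standard benchmark; ``"obscure"`` — identical
        except the true compounds are rarer than the decoys
        (``truth_ds_bias=0.2``), the regime where metadata ranking hurts;
        ``"noiseless"`` — collision-free masses, zero acquisition noise and
        no metadata bias, the perfect-recovery limit.
        """
        presets: dict[str, dict] = {
            "default": {},
            "obscure": {"truth_ds_bias": 0.2},
            "noiseless": {
                "isobaric_group_fraction": 0.0,
                "truth_ds_bias": 1.0,
                "dropout_p": 0.0,
                "mz_jitter_sd": 0.0,
                "intensity_cv": 0.0,
                "contaminant_rate": 0.0,
            },
        }
        if name not in presets:
            raise ConfigError(f"unknown preset {name!r}; choose from {sorted(presets)}")
        kwargs = dict(presets[name])
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["mass_range"] = list(self.mass_range)
        data["fragments_per_compound"] = list(self.fragments_per_compound)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a flat key-value mapping")
        for key in ("mass_range", "fragments_per_compound"):
            if key in data:
                data[key] = tuple(data[key])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class SimulatedQuery:
    """One noisy query with its ground truth."""

    query_id: str
    true_compound_id: str
    merged: Spectrum
    per_energy: dict[int, Spectrum] = field(default_factory=dict)


@dataclass
class Benchmark:
    """In-memory benchmark: the library plus queries with known answers."""

    config: SyntheticConfig
    library: SpectralLibrary
    queries: list[SimulatedQuery]

    @property
    def truth(self) -> dict[str, str]:
        return {q.query_id: q.true_compound_id for q in self.queries}


def _streams(config: SyntheticConfig):
    root = np.random.SeedSequence(config.seed)
    return root.spawn(4)  # structure, spectra, truth, queries


def _compound_id(i: int) -> str:
    return f"SYN{i:05d}"


def select_truths(config: SyntheticConfig) -> list[str]:
    """The true compound of each query; deterministic in the config seed."""
    _, _, s_truth, _ = _streams(config)
    rng = np.random.default_rng(s_truth)
    replace = config.n_queries > config.n_compounds
    idx = rng.choice(config.n_compounds, size=config.n_queries, replace=replace)
    return [_compound_id(int(i)) for i in idx]


def _cluster_sizes(config: SyntheticConfig, rng: np.random.Generator) -> list[int]:
    n_iso = int(round(config.isobaric_group_fraction * config.n_compounds))
    if n_iso < 2:
        return []
    sizes: list[int] = []
    remaining = n_iso
    while remaining >= 2:
        size = 2 + min(int(rng.geometric(0.45)) - 1, 10)
        size = min(size, remaining)
        if remaining - size == 1:
            size += 1  # absorb the leftover single compound
        sizes.append(size)
        remaining -= size
    return sizes


def _draw_base_masses(
    n: int, config: SyntheticConfig, rng: np.random.Generator
) -> list[float]:
    lo, hi = config.mass_range
    masses: list[float] = []
    min_rel = _MIN_SEPARATION_PPM * 1e-6
    attempts = 0
    limit = 500 * max(n, 1)
    while len(masses) < n:
        attempts += 1
        if attempts > limit:
            raise ConfigError(
                f"cannot place {n} masses in {config.mass_range} with "
                f"{_MIN_SEPARATION_PPM} ppm separation; widen the mass range"
            )
        m = float(rng.uniform(lo, hi))
        i = int(np.searchsorted(masses, m))
        near = []
        if i > 0:
            near.append(masses[i - 1])
        if i < len(masses):
            near.append(masses[i])
        if all(abs(m - x) / x > min_rel for x in near):
            masses.insert(i, m)
    rng.shuffle(masses)
    return masses


def _random_block(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def toy_fragment_spectrum(
    mass: float,
    energy: int,
    rng: np.random.Generator,
    fragments_per_compound: tuple[int, int] = (5, 15),
    compound_id: str = "toy",
) -> Spectrum:
    """Toy in-silico fragmentation of a neutral mass at one collision energy.

    Fragment ions sit at uniformly drawn fractions of the precursor mass
    (protonated); their base intensities are fixed per compound while the
    energy controls (a) the surviving precursor intensity, which decreases
    with energy, and (b) an exponential tilt that boosts low-mass fragments
    as energy rises.  The precursor's share of the total ion current equals
    :data:`PRECURSOR_SURVIVAL` at each energy exactly.

    The caller must pass a freshly-seeded ``rng`` per (compound, energy)
    call — re-seeding with the same per-compound stream for every energy
    keeps the fragment positions shared across energies, as in real
    energy-resolved acquisitions of one compound.
    """
    if energy not in ENERGY_LEVELS:
        raise DomainError(f"energy must be one of {ENERGY_LEVELS}, got {energy}")
    f_lo, f_hi = fragments_per_compound
    n_frag = int(rng.integers(f_lo, f_hi + 1))
    fractions = np.sort(rng.uniform(0.08, 0.92, size=n_frag))
    bases = rng.uniform(0.2, 1.0, size=n_frag)
    survival = PRECURSOR_SURVIVAL[energy]
    tilt = LOW_MASS_TILT[energy]
    weights = bases * np.exp(-tilt * fractions)
    frag_int = (1.0 - survival) * weights / weights.sum()
    mz = np.append(fractions * mass + PROTON_MASS, mass + PROTON_MASS)
    inten = np.append(frag_int, survival)
    inten = inten / inten.max() * 100.0
    peaks = tuple(Peak(float(m), float(i)) for m, i in zip(mz, inten))
    return Spectrum(
        f"{compound_id}_e{energy}", mass + PROTON_MASS, "positive", peaks, energy
    )


def generate_library(config: SyntheticConfig) -> SpectralLibrary:
    """Generate the synthetic compound library with predicted spectra.

    Cluster members share a neutral mass within a few ppm (guaranteeing
    multi-candidate precursor sets) and an InChIKey skeleton (stereoisomer
    emulation, exercising the curation audit); every compound receives
    predicted spectra at 10/20/40 eV.
    """
    s_struct, s_spectra, _, _ = _streams(config)
    rng = np.random.default_rng(s_struct)
    n = config.n_compounds

    sizes = _cluster_sizes(config, rng)
    n_clustered = sum(sizes)
    n_singleton = n - n_clustered
    bases = _draw_base_masses(len(sizes) + n_singleton, config, rng)
    spread = _CLUSTER_SPREAD_PPM * 1e-6

    masses: list[float] = []
    skeleton_group: list[int] = []  # group index, -1 for singletons
    for g, size in enumerate(sizes):
        base = bases[g]
        for _ in range(size):
            masses.append(base * (1.0 + float(rng.uniform(-spread, spread))))
            skeleton_group.append(g)
    for j in range(n_singleton):
        masses.append(bases[len(sizes) + j])
        skeleton_group.append(-1)

    group_skeletons: dict[int, str] = {
        g: _random_block(rng, 14) for g in range(len(sizes))
    }
    used_keys: set[str] = set()
    inchikeys: list[str] = []
    for i in range(n):
        g = skeleton_group[i]
        skeleton = group_skeletons[g] if g >= 0 else _random_block(rng, 14)
        key = f"{skeleton}-{_random_block(rng, 8)}SA-N"
        while key in used_keys:
            key = f"{skeleton}-{_random_block(rng, 8)}SA-N"
        used_keys.add(key)
        inchikeys.append(key)

    truth_ids = set(select_truths(config))
    zipf = np.minimum(rng.zipf(config.ds_zipf_exponent, size=n), 10**6)
    pubmed = np.minimum(rng.zipf(2.0, size=n), 10**6)
    pubchem = np.minimum(rng.zipf(2.0, size=n), 10**6)
    norman = rng.random(n) < 0.25

    records: list[CompoundRecord] = []
    for i in range(n):
        cid = _compound_id(i)
        ds = int(zipf[i])
        if cid in truth_ids:
            ds = int(round(ds * config.truth_ds_bias))
        records.append(
            CompoundRecord(
                compound_id=cid,
                monoisotopic_mass=masses[i],
                name=f"synthetic-{i:05d}",
                inchikey=inchikeys[i],
                ds_count=ds,
                pubmed_count=int(pubmed[i]),
                pubchem_sources=int(pubchem[i]),
                norman_susdat=bool(norman[i]),
            )
        )

    predicted: list[tuple[str, PredictedSpectrumSet]] = []
    for i, comp_ss in enumerate(s_spectra.spawn(n)):
        cid = _compound_id(i)
        spectra = {
            e: toy_fragment_spectrum(
                masses[i],
                e,
                np.random.default_rng(comp_ss),
                config.fragments_per_compound,
                compound_id=cid,
            )
            for e in ENERGY_LEVELS
        }
        predicted.append((cid, PredictedSpectrumSet(cid, spectra)))
    return build_library(records, predicted)


def simulate_query(
    library: SpectralLibrary,
    true_compound_id: str,
    config: SyntheticConfig,
    query_seed,
    query_id: str = "query",
) -> SimulatedQuery:
    """Simulate one noisy acquisition of a known compound.

    Starts from the compound's predicted spectra, applies per-peak dropout,
    Gaussian m/z jitter, multiplicative lognormal intensity noise (of the
    configured coefficient of variation) and Poisson contaminant peaks at
    random m/z, then merges the per-energy peak lists into the
    challenge-style merged spectrum.  If every peak is dropped the draw is
    resampled once; a second empty draw raises :class:`DomainError`.
    """
    pset = library.predicted.get(true_compound_id)
    if pset is None or len(pset) == 0:
        raise ConfigError(
            f"true compound {true_compound_id!r} has no predicted spectra"
        )
    rng = np.random.default_rng(query_seed)
    ion_mz = library.records[true_compound_id].monoisotopic_mass + PROTON_MASS
    precursor = ion_mz * (1.0 + float(rng.normal(0.0, _PRECURSOR_JITTER_REL)))
    sigma = math.sqrt(math.log(1.0 + config.intensity_cv**2))
    per_energy: dict[int, Spectrum] = {}
    for attempt in range(2):
        per_energy = {}
        for energy in sorted(pset.spectra):
            spec = pset.spectra[energy]
            n = len(spec)
            # All noise vectors are drawn at full peak-list size before the
            # dropout mask is applied, so benchmarks with the same seed but
            # different noise levels stay coupled (e.g. raising dropout_p
            # removes peaks from an otherwise identical realisation).
            keep = rng.random(n) >= config.dropout_p
            jitter = rng.normal(0.0, config.mz_jitter_sd, size=n) if config.mz_jitter_sd > 0 else np.zeros(n)
            factors = (
                rng.lognormal(-0.5 * sigma**2, sigma, size=n)
                if config.intensity_cv > 0
                else np.ones(n)
            )
            mz = (spec.mz + jitter)[keep]
            inten = (spec.intensity * factors)[keep]
            k = int(rng.poisson(config.contaminant_rate / len(ENERGY_LEVELS)))
            if k:
                lo = min(50.0, 0.3 * precursor)
                mz = np.append(mz, rng.uniform(lo, precursor + 1.0, size=k))
                inten = np.append(inten, rng.uniform(1.0, 15.0, size=k))
            if len(mz) == 0:
                continue
            per_energy[energy] = Spectrum(
                f"{query_id}_e{energy}",
                precursor,
                "positive",
                tuple(Peak(float(m), float(x)) for m, x in zip(mz, inten)),
                energy,
            )
        if per_energy:
            break
    if not per_energy:
        raise DomainError(
            f"query for {true_compound_id!r}: all peaks dropped twice "
            f"(dropout_p={config.dropout_p})"
        )
    merged = merge_spectra(per_energy.values(), query_id, precursor, "positive")
    return SimulatedQuery(query_id, true_compound_id, merged, per_energy)


def make_benchmark(config: SyntheticConfig) -> Benchmark:
    """Generate the full in-memory benchmark (library + queries + truth)."""
    library = generate_library(config)
    truths = select_truths(config)
    _, _, _, s_query = _streams(config)
    queries = [
        simulate_query(library, cid, config, qss, query_id=f"Q{i:04d}")
        for i, (cid, qss) in enumerate(zip(truths, s_query.spawn(config.n_queries)))
    ]
    return Benchmark(config, library, queries)


def generate_benchmark(config: SyntheticConfig, out_dir) -> dict[str, Path]:
    """Write a complete on-disk benchmark consumable by the CLI chain.

    Produces ``library.msp``, ``metadata.csv``, one merged query file per
    acquisition under ``queries/``, and ``truth.csv`` mapping query ids to
    the true compound ids.  Deterministic: the same config yields
    byte-identical files.
    """
    from .io_formats import write_library_msp, write_metadata_csv, write_query_spectrum

    out = Path(out_dir)
    (out / "queries").mkdir(parents=True, exist_ok=True)
    bench = make_benchmark(config)
    lib = bench.library
    ordered_ids = sorted(lib.records)
    paths = {
        "library_msp": out / "library.msp",
        "metadata_csv": out / "metadata.csv",
        "truth_csv": out / "truth.csv",
        "queries_dir": out / "queries",
        "config_yaml": out / "config.yaml",
    }
    write_library_msp(
        [(cid, lib.predicted[cid]) for cid in ordered_ids if cid in lib.predicted],
        paths["library_msp"],
    )
    write_metadata_csv([lib.records[cid] for cid in ordered_ids], paths["metadata_csv"])
    for q in bench.queries:
        write_query_spectrum(q.merged, paths["queries_dir"] / f"{q.query_id}.txt")
    pd.DataFrame(
        [{"query_id": q.query_id, "compound_id": q.true_compound_id} for q in bench.queries]
    ).to_csv(paths["truth_csv"], index=False)
    config.to_yaml(paths["config_yaml"])
    return paths
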