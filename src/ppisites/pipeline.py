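"""End-to-end drivers: featurize a benchmark and run the CV protocols.

These helpers wire the modules together for the synthetic benchmarks:
structure -> interface labels -> 217-dim pair features -> (optional) signal
injection from generator truth -> sample selection -> balanced training ->
leave-one-complex-out or k-fold evaluation.
"""

from __future__ import annotations

import numpy as np

from .cnn import PairCNNClassifier
from .datasets import FeaturizedComplex, build_dataset
from .evaluation import EvalReport, kfold_cv, loco_cv
from .features import PairFeaturizer
from .interface import InterfaceParams, label_pairs
from .structure import SurfaceParams
from .synth import BenchmarkComplex, SynthSpec, inject_signal, make_benchmark


def featurize_benchmark(complexes: list[BenchmarkComplex], spec: SynthSpec,
                        surface_params: SurfaceParams | None = None,
                        seed: int = 0) -> list[FeaturizedComplex]:
    """Compute labelled pair features for generated complexes.

    Feature-space class signal (strength/noise from the spec) is injected on
    the profile and structure blocks of *dominant* planted contacts, using
    the generator's ground truth.
    """
    feat = PairFeaturizer(surface_params or SurfaceParams())
    iface = InterfaceParams(spec.cutoff)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2077]))
    out = []
    for bc in complexes:
        pairs = label_pairs(bc.structure, iface)
        X, y = feat.featurize_pairs(bc.structure, bc.profiles, pairs)
        dominant = {c for c, d in zip(bc.truth.contacts, bc.truth.dominant) if d}
        mask = np.array([(pl.r_key[1], pl.l_key[1]) in dominant for pl in pairs])
        X = inject_signal(X, mask, spec.signal_strength, spec.noise, rng)
        out.append(FeaturizedComplex(bc.truth.pdb_id, pairs, X, y))
    return out


def default_estimator(epochs: int = 150, batch_size: int = 32, seed: int = 0) -> PairCNNClassifier:
    """Benchmark-scale classifier configuration (small data, more epochs)."""
    return PairCNNClassifier(epochs=epochs, batch_size=batch_size, random_state=seed)


def run_loco_benchmark(spec: SynthSpec, estimator=None, filter_mode: str = "none",
                       high: set[tuple[str, str]] | None = None,
                       n_subsets: int = 1, seed: int = 0) -> EvalReport:
    """Generate a benchmark and evaluate it leave-one-complex-out."""
    complexes = make_benchmark(spec)
    featurized = featurize_benchmark(complexes, spec, seed=seed)
    if filter_mode == "high_propensity" and high is None:
        high = truth_high_pairs(spec)
    datasets = build_dataset(featurized, filter_mode=filter_mode, high=high, seed=seed)
    estimator = estimator or default_estimator(seed=seed)
    return loco_cv(datasets, estimator, n_subsets=n_subsets, seed=seed)


def run_kfold_benchmark(spec: SynthSpec, estimator=None, k: int = 5,
                        filter_mode: str = "none",
                        high: set[tuple[str, str]] | None = None,
                        n_subsets: int = 1, seed: int = 0) -> EvalReport:
    complexes = make_benchmark(spec)
    featurized = featurize_benchmark(complexes, spec, seed=seed)
    if filter_mode == "high_propensity" and high is None:
        high = truth_high_pairs(spec)
    datasets = build_dataset(featurized, filter_mode=filter_mode, high=high, seed=seed)
    estimator = estimator or default_estimator(seed=seed)
    return kfold_cv(datasets, estimator, k=k, seed=seed, n_subsets=n_subsets)


def truth_high_pairs(spec: SynthSpec) -> set[tuple[str, str]]:
    """The generator's designated high-propensity type pairs (both orientations)."""
    if spec.high_aa_pairs is None:
        raise ValueError("spec has no designated high-propensity pair set")
    out = set()
    for a, b in spec.high_aa_pairs:
        out.add((a, b))
        out.add((b, a))
    return out
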