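"""Synthetic data sets with known generative models, for tests and benchmarks.

Real CGMD-labelled descriptor tables cannot ship with the package, so every
evaluation here runs against data whose ground truth is known by
construction: regression fixtures (linear, RBF-mixture, or Judred-driven
labels over seeded Gaussian features) and summaries of the synthetic AP
landscape over random sequence samples.  Every fixture is a pure function
of its spec, so any experiment that names its spec and seed is exactly
reproducible.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .judred import JudredCalculator
from .oracle import SyntheticOracleConfig, true_ap
from .peptides import sample_space, space_size, enumerate_space


@dataclass(frozen=True)
class FixtureSpec:
    """Names one reproducible synthetic regression data set."""

    generator_id: str  # linear | rbf-mixture | judred
    n: int
    n_features: int = 10
    noise_sd: float = 0.0
    seed: int = 0
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def make_regression_fixture(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate ``(X, y, ground_truth_params)`` from a named generative model.

    * ``linear``: ``y = X @ coef + noise`` with a sparse coefficient vector
      (``params["coef"]`` maps column index -> weight; default ``{0: 3, 1: -2}``);
    * ``rbf-mixture``: y is a sum of Gaussian bumps at known centres, a
      target an RBF machine with matched kernel width should master;
    * ``judred``: X is the Judred matrix of ``n`` random peptides of
      ``params["length"]`` (default 3) and y their synthetic true AP —
      the stand-in for a real descriptor/AP table.
    """
    if spec.n < 10:
        raise ValueError(f"fixture needs n >= 10, got {spec.n}")
    rng = np.random.default_rng(spec.seed)
    if spec.generator_id == "linear":
        coef_map = dict(spec.params.get("coef", {0: 3.0, 1: -2.0}))
        X = rng.standard_normal((spec.n, spec.n_features))
        coef = np.zeros(spec.n_features)
        for j, w in coef_map.items():
            coef[int(j)] = w
        y = X @ coef + spec.noise_sd * rng.standard_normal(spec.n)
        truth = {"coef": coef, "informative": sorted(int(j) for j in coef_map)}
    elif spec.generator_id == "rbf-mixture":
        n_centres = int(spec.params.get("n_centres", 3))
        width = float(spec.params.get("width", 1.0))
        X = rng.standard_normal((spec.n, spec.n_features))
        centres = rng.standard_normal((n_centres, spec.n_features))
        amps = rng.uniform(1.0, 2.0, n_centres)
        d2 = ((X[:, None, :] - centres[None, :, :]) ** 2).sum(-1)
        y = (np.exp(-d2 / (2 * width**2)) * amps).sum(1)
        y = y + spec.noise_sd * rng.standard_normal(spec.n)
        truth = {"centres": centres, "amplitudes": amps, "width": width}
    elif spec.generator_id == "judred":
        length = int(spec.params.get("length", 3))
        peps = sample_space(length, spec.n, random.Random(spec.seed))
        calc = JudredCalculator()
        X = calc.matrix(peps)
        cfg = SyntheticOracleConfig()
        y = np.array([true_ap(p, cfg) for p in peps])
        y = y + spec.noise_sd * rng.standard_normal(spec.n)
        truth = {"peptides": peps, "oracle_config": cfg}
    else:
        raise ValueError(f"unknown generator_id {spec.generator_id!r}")
    return X, y, truth


def add_distractors(
    X: np.ndarray, n_distractors: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Append pure-noise columns; returns (augmented X, informative-column mask)."""
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((len(X), n_distractors))
    mask = np.r_[np.ones(X.shape[1], bool), np.zeros(n_distractors, bool)]
    return np.hstack([X, noise]), mask


def landscape_summary(
    config: SyntheticOracleConfig | None = None,
    length: int = 3,
    n_sample: int = 800,
    seed: int = 0,
) -> dict:
    """Noise-free AP statistics over a seeded random sample of the space.

    800-peptide random samples are the conventional probe for
    characterising a length's AP distribution; when ``n_sample`` covers the
    whole space the summary is exact population statistics.
    """
    cfg = config or SyntheticOracleConfig()
    total = space_size(length)
    if n_sample > total:
        raise ValueError(f"n_sample {n_sample} exceeds space size {total}")
    if n_sample == total:
        peps = list(enumerate_space(length))
    else:
        peps = sample_space(length, n_sample, random.Random(seed))
    aps = np.array([true_ap(p, cfg) for p in peps])
    return {
        "length": length,
        "n_sample": n_sample,
        "mean": float(aps.mean()),
        "max": float(aps.max()),
        "min": float(aps.min()),
        "range": float(aps.max() - aps.min()),
    }


def brute_force_top(length: int, k: int, config: SyntheticOracleConfig | None = None) -> list[str]:
    """The true top-*k* peptides of a length by exhaustive noise-free evaluation.

    The independent reference for discovery curves; feasible up to L = 4.
    """
    cfg = config or SyntheticOracleConfig()
    peps = enumerate_space(length)
    return sorted(peps, key=lambda p: (-true_ap(p, cfg), p))[:k]


def al_screening_trial(
    seed: int,
    length: int = 3,
    iterations: int = 15,
    batch_size: int = 10,
    reference_top: list[str] | None = None,
    oracle_config: SyntheticOracleConfig | None = None,
    calculator=None,
) -> dict:
    """One paired active-learning vs screening comparison at equal oracle budget.

    Runs the two-step loop (seed homopolymer + ``iterations * batch_size``
    in-loop labels), then the one-shot screening baseline spending the same
    total number of oracle calls (training set sized to make up the
    difference), both against the same synthetic oracle.  Also builds the
    discovery curves for the true top peptides: the loop's labelling order
    versus a uniformly random labelling order of equal budget.

    Returns per-trial summaries: all-inclusive mean labelled AP for both
    strategies, the discovery-curve fractions, whether the loop's curve
    weakly dominates random screening at every budget point, the
    least-squares slope of per-iteration mean AP, and the mean AP of labels
    from iteration 5 onward (the converged phase).
    """
    from . import active_learning as al
    from .oracle import SyntheticOracle

    cfg = (oracle_config or SyntheticOracleConfig()).with_seed(seed)
    oracle = SyntheticOracle(cfg)
    run_cfg = al.RunConfig(
        length=length, batch_size=batch_size, max_iterations=iterations, rng_seed=seed
    )
    record = al.run(run_cfg, oracle=oracle, calculator=calculator)
    total_budget = len(record.training)

    space = list(enumerate_space(length))
    screening = al.screening_baseline(
        train_size=total_budget - batch_size,
        top_k=batch_size,
        space=space,
        oracle=oracle,
        seed=seed,
        calculator=calculator,
    )

    ref = reference_top or brute_force_top(length, 20, cfg)
    al_order = al.run_labelled_order(record)
    al_curve = al.discovery_curve(al_order, ref)
    rng = random.Random(seed + 10_000)
    random_order = rng.sample(space, len(al_order))
    random_curve = al.discovery_curve(random_order, ref)
    dominates = all(a >= r for (_, a), (_, r) in zip(al_curve, random_curve))

    means = record.per_iteration_mean_ap()
    slope = float(np.polyfit(np.arange(len(means)), means, 1)[0])
    late = [
        ap
        for rec in record.iterations[4:]
        for ap in rec.measured.values()
    ]
    return {
        "seed": seed,
        "al_mean_ap": float(np.mean(record.training.aps)),
        "screening_mean_ap": screening["mean_ap_all_labels"],
        "oracle_calls": record.oracle_calls,
        "total_budget": total_budget,
        "al_found_fraction": al_curve[-1][1],
        "random_found_fraction": random_curve[-1][1],
        "al_curve": al_curve,
        "random_curve": random_curve,
        "curve_dominates_random": bool(dominates),
        "iteration_mean_slope": slope,
        "late_mean_ap": float(np.mean(late)),
    }


def al_screening_experiment(
    n_seeds: int = 20,
    length: int = 3,
    iterations: int = 15,
    batch_size: int = 10,
    base_seed: int = 0,
    oracle_config: SyntheticOracleConfig | None = None,
) -> dict:
    """Paired Monte-Carlo benchmark over seeds (the discovery-efficiency study).

    Aggregates :func:`al_screening_trial` over ``n_seeds`` paired seeds and
    reports win counts: how often active learning beats equal-budget
    screening on mean labelled AP, and how often its discovery curve weakly
    dominates random screening at every budget point.
    """
    from .judred import JudredCalculator

    cfg = oracle_config or SyntheticOracleConfig()
    ref = brute_force_top(length, 20, cfg)
    calc = JudredCalculator()
    space_mean = float(
        np.mean([true_ap(p, cfg) for p in enumerate_space(length)])
    )
    trials = [
        al_screening_trial(
            base_seed + i, length, iterations, batch_size,
            reference_top=ref, oracle_config=cfg, calculator=calc,
        )
        for i in range(n_seeds)
    ]
    return {
        "trials": trials,
        "n_seeds": n_seeds,
        "space_mean_true_ap": space_mean,
        "al_mean_wins": sum(t["al_mean_ap"] > t["screening_mean_ap"] for t in trials),
        "curve_dominance_wins": sum(t["curve_dominates_random"] for t in trials),
        "positive_slope_count": sum(t["iteration_mean_slope"] > 0 for t in trials),
        "late_exceeds_space_mean_by_03": sum(
            t["late_mean_ap"] >= space_mean + 0.3 for t in trials
        ),
        "mean_al_found_fraction": float(
            np.mean([t["al_found_fraction"] for t in trials])
        ),
        "mean_random_found_fraction": float(
            np.mean([t["random_found_fraction"] for t in trials])
        ),
    }


def dump_fixture(path_prefix: str, spec: FixtureSpec) -> None:
    """Write a fixture as ``<prefix>.csv`` plus a ``<prefix>.spec.json`` sidecar."""
    X, y, _ = make_regression_fixture(spec)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    df["y"] = y
    df.to_csv(f"{path_prefix}.csv", index=False)
    with open(f"{path_prefix}.spec.json", "w") as fh:
        fh.write(spec.to_json())


def load_fixture(path_prefix: str) -> tuple[np.ndarray, np.ndarray, FixtureSpec]:
    with open(f"{path_prefix}.spec.json") as fh:
        d = json.load(fh)
    spec = FixtureSpec(**d)
    df = pd.read_csv(f"{path_prefix}.csv")
    return df.drop(columns="y").to_numpy(), df["y"].to_numpy(), spec
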