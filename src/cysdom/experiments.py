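"""Simulation experiments: recovery benchmarks run by the analysis scripts.

Each function is a self-contained, seeded experiment returning plain
numbers, so the narrative analysis drivers, the test suite, and the
reproduction script can all call the same code.
"""

from __future__ import annotations

import numpy as np

from .align import Msa
from .jtt import jtt_ml_distance, stationary_frequencies, transition_matrix
from .jtt_data import AA_ORDER
from .phylo import distance_matrix, has_bipartition, neighbor_joining
from .signature import annotate
from .synthetic import SimulationConfig, evolve_sequence, simulate_family, truth_matches_architecture

#: The two-group duplication topology over paralog domains: the first
#: duplication separates D1-type from D2-type domains, the later
#: (four-domain) duplication splits within each group.
MATCHED_TOPOLOGY_LEAVES = ("P1.D1", "P2.D1", "P1.D2", "P2.D2")


def sample_equilibrium_sequence(rng: np.random.Generator, n_sites: int) -> str:
    pi = stationary_frequencies()
    return "".join(AA_ORDER[i] for i in rng.choice(20, n_sites, p=pi))


def evolve_fast(seq: str, t: float, rng: np.random.Generator) -> str:
    """Vectorized unconstrained JTT evolution (for long benchmark sequences)."""
    if t == 0:
        return seq
    P = transition_matrix(t)
    idx = np.fromiter((AA_ORDER.index(ch) for ch in seq), dtype=int, count=len(seq))
    cum = P.cumsum(axis=1)
    u = rng.random(len(seq))
    new = (u[:, None] > cum[idx]).sum(axis=1)
    return "".join(AA_ORDER[i] for i in new)


def duplication_recovery_rate(
    n_runs: int = 100,
    branch_t: float = 0.5,
    n_sites: int = 300,
    seed: int = 0,
) -> float:
    """Fraction of simulated domain families whose NJ tree recovers the
    duplication bipartition {P1.D1, P2.D1} | {P1.D2, P2.D2}.

    One family = an ancestral domain duplicated into a D1-type and a
    D2-type lineage, each then split into two paralogs; every branch
    evolves for ``branch_t`` substitutions/site over ``n_sites`` sites.
    """
    hits = 0
    for k in range(n_runs):
        rng = np.random.default_rng(seed + k)
        anc = sample_equilibrium_sequence(rng, n_sites)
        group1 = evolve_fast(anc, branch_t, rng)
        group2 = evolve_fast(anc, branch_t, rng)
        leaves = {
            "P1.D1": evolve_fast(group1, branch_t, rng),
            "P2.D1": evolve_fast(group1, branch_t, rng),
            "P1.D2": evolve_fast(group2, branch_t, rng),
            "P2.D2": evolve_fast(group2, branch_t, rng),
        }
        msa = Msa(labels=tuple(leaves), rows=tuple(leaves.values()))
        tree = neighbor_joining(distance_matrix(msa))
        hits += has_bipartition(tree, {"P1.D1", "P2.D1"})
    return hits / n_runs


def zero_noise_recovery_rate(n_families: int = 200, seed: int = 0) -> float:
    """Fraction of zero-divergence families whose scanner annotation equals
    the generator's ground truth exactly (domains, partial, CTM)."""
    hits = 0
    for k in range(n_families):
        fam = simulate_family(SimulationConfig(seed=seed + k, branch_time=0.0))
        ok = all(
            truth_matches_architecture(fam.truth_architectures[rec.id], annotate(rec))
            for rec in fam.records
        )
        hits += ok
    return hits / n_families


def jtt_time_recovery(
    t_true: float = 0.5,
    n_sites: int = 1000,
    n_replicates: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """(mean, sd) of ML distance estimates on pairs simulated at ``t_true``."""
    rng = np.random.default_rng(seed)
    est = []
    for _ in range(n_replicates):
        anc = sample_equilibrium_sequence(rng, n_sites)
        b = evolve_fast(anc, t_true, rng)
        est.append(jtt_ml_distance(anc, b))
    return float(np.mean(est)), float(np.std(est))
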