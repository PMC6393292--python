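"""Shared fixtures: one large simulated ensemble per condition, reused
session-wide so the statistical tests do not re-simulate per test."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import okaseq as ok

BASE_SEED = 3
N_LARGE = 50_000


@pytest.fixture(scope="session")
def base_config() -> ok.SimulationConfig:
    return ok.SimulationConfig(seed=BASE_SEED, n_fragments=N_LARGE)


@pytest.fixture(scope="session")
def top_dyads(base_config) -> ok.FeatureSet:
    dyads, _, _ = ok.build_genome(base_config)
    return ok.select_top_occupied(dyads, 0.5)


@pytest.fixture(scope="session")
def sims(base_config) -> dict[str, tuple[list, ok.GroundTruth]]:
    """Large ensembles for the conditions the statistical tests exercise."""
    out = {}
    for cond in ("WT", "dna2", "exo1", "rad27"):
        config = dataclasses.replace(base_config, condition=cond)
        out[cond] = ok.simulate_fragments(config)
    return out


@pytest.fixture(scope="session")
def flap_sim(base_config) -> tuple[list, ok.GroundTruth]:
    """Strand-displacement scenario: flap length mean 15 nt (1 + Poisson(14))."""
    config = dataclasses.replace(
        base_config, decoupled_flap_mode=True, gap_flap_len_mean=14.0
    )
    return ok.simulate_fragments(config)


def dyad_profile(records, features, end_kind, window=100, smooth=5, norm="max"):
    """The standard composite-profile pipeline used throughout the tests."""
    p = ok.aggregate_termini(records, features, end_kind, window)
    p = ok.smooth_profile(p, smooth)
    return ok.normalize_profile(p, norm)


def aggregate_oracle(fragments, features, end_kind, window):
    """Exhaustive double-loop aggregation, written independently of
    okaseq.profiles: inline terminus math, no searchsorted, no vector ops."""
    counts = np.zeros(2 * window + 1, dtype=np.int64)
    for f in fragments:
        if f.strand == "+":
            t = f.start if end_kind == "five_prime" else f.end - 1
            sign = 1
        else:
            t = f.end - 1 if end_kind == "five_prime" else f.start
            sign = -1
        for feat in features:
            if feat.chrom == f.chrom and abs(t - feat.midpoint) <= window:
                counts[(t - feat.midpoint) * sign + window] += 1
    return counts


def ligate_oracle_geometry(fragments):
    """Brute-force merge: repeatedly scan all pairs, merge any two abutting
    same-chrom same-strand intervals, until fixpoint. Ignores annotations."""
    frags = [(f.chrom, f.start, f.end, f.strand) for f in fragments]
    changed = True
    while changed:
        changed = False
        for i, a in enumerate(frags):
            for j, b in enumerate(frags):
                if i == j or a[0] != b[0] or a[3] != b[3]:
                    continue
                if b[1] == a[2]:  # b starts where a ends
                    frags[i] = (a[0], a[1], b[2], a[3])
                    del frags[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(frags)


def ligation_signal_oracle(fragments, size_cutoff=1000):
    """Independent percent-lost computation for annotated ensembles: group
    by (chrom, strand), sort, split into runs at non-nick 5'-end states,
    sum run lengths, count molecules below the cutoff."""
    groups = {}
    for f in fragments:
        groups.setdefault((f.chrom, f.strand), []).append(f)
    pre = sum(1 for f in fragments if f.end - f.start < size_cutoff)
    post = 0
    for (chrom, strand), frs in groups.items():
        frs.sort(key=lambda f: (f.start, f.end, f.name))
        runs = [[frs[0]]]
        for prev, cur in zip(frs, frs[1:]):
            side = cur if strand == "+" else prev
            if side.junction_state == "nick":
                runs[-1].append(cur)
            else:
                runs.append([cur])
        for run in runs:
            if sum(f.end - f.start for f in run) < size_cutoff:
                post += 1
    return 100.0 * (pre - post) / pre
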