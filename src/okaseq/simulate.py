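"""Synthetic lagging-strand fragment ensembles with full ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, not replication biochemistry:

* a genome of one or more chromosomes with nucleosome dyads tiled every
  ``nucleosome_repeat`` nt and occupancy scores drawn from a gamma
  distribution (so "top fraction by occupancy" filtering is exercisable);
* explicit replication origins that partition the genome into rightward
  (``+``) and leftward (``-``) fork domains, with domain boundaries at
  inter-origin midpoints; fragment strand equals local fork direction, so
  synthesis proceeds left-to-right on ``+`` domains;
* 3' termini placed at the assigned dyad plus a condition-dependent signed
  shift and Gaussian noise, in synthesis orientation (negative shift =
  toward the replication-fork-proximal nucleosome edge, i.e. reduced nick
  translation);
* fragment lengths phased to the nucleosome repeat: ``k * repeat + noise``
  with ``k`` in {1, 2, 3} (the mono-/di-/tri-nucleosome ladder seen on
  alkaline gels); the 5' terminus sits ``length - 1`` nt upstream of the 3'
  terminus in synthesis direction;
* a junction state at each 5' end: ligatable nick with probability
  ``ligatable_fraction``, otherwise a gap or flap (equal odds) of length
  ``1 + Poisson(gap_flap_len_mean)``;
* "hard barrier" transcription-factor sites: a fragment assigned within one
  repeat of a TF site relocates its 3' terminus to the fork-proximal site
  edge with probability ``tf_barrier_weight``;
* an alternative ``decoupled_flap_mode`` in which 3' termini stay at their
  wild-type positions while every 5' terminus extends upstream by an
  unprocessed flap length -- the "ongoing strand displacement" scenario, as
  opposed to the default coupled-shift (reduced nick translation) scenario.

Identical configuration (including seed) yields bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from okaseq.fragments import Feature, FeatureSet, FragmentRecord, write_features, write_fragments

#: The eight nuclease-depletion conditions: every combination of Rad27
#: depletion, Dna2 depletion and EXO1 deletion (DNA ligase co-depleted in all).
CONDITIONS = (
    "WT", "rad27", "exo1", "dna2",
    "rad27_exo1", "rad27_dna2", "exo1_dna2", "triple",
)

# Sub-stream tags so genome and fragment draws are independent of each other
# and fragment draws are independent across conditions.
_GENOME_STREAM = 101
_FRAGMENT_STREAM = 211


def _default_chrom_lengths() -> dict[str, int]:
    return {"chrS1": 1_000_000}


def _default_origins() -> list[tuple[str, int]]:
    return [("chrS1", 50_000 + 100_000 * k) for k in range(10)]


def _default_tf_sites() -> list[tuple[str, int, str]]:
    return [("chrS1", 5_000 + 10_000 * k, "+" if k % 2 == 0 else "-") for k in range(100)]


def _default_shift() -> dict[str, float]:
    # Signed nt, synthesis orientation; negative = toward the fork-proximal
    # nucleosome edge (reduced nick translation). Magnitudes are free
    # parameters ordered by the qualitative severity of each depletion.
    return {
        "WT": 0.0, "rad27": -20.0, "exo1": -10.0, "dna2": 0.0,
        "rad27_exo1": -30.0, "rad27_dna2": -20.0, "exo1_dna2": -10.0,
        "triple": -30.0,
    }


def _default_sd() -> dict[str, float]:
    return {c: 15.0 for c in CONDITIONS}


def _default_ligatable() -> dict[str, float]:
    # Rad27-proficient strains leave most junctions as sealable nicks;
    # Rad27-depleted strains leave essentially none.
    return {
        "WT": 0.9, "rad27": 0.05, "exo1": 0.8, "dna2": 0.9,
        "rad27_exo1": 0.02, "rad27_dna2": 0.02, "exo1_dna2": 0.75,
        "triple": 0.02,
    }


@dataclass
class SimulationConfig:
    """Every generative parameter plus the seed; fully serializable.

    Units are nucleotides unless stated. ``terminus_shift``, ``terminus_sd``
    and ``ligatable_fraction`` are per-condition maps; ``condition`` selects
    the active entry.
    """

    chrom_lengths: dict[str, int] = field(default_factory=_default_chrom_lengths)
    origin_positions: list[tuple[str, int]] = field(default_factory=_default_origins)
    nucleosome_repeat: int = 165
    dyad_jitter_sd: float = 15.0
    n_fragments: int = 50_000
    condition: str = "WT"
    terminus_shift: dict[str, float] = field(default_factory=_default_shift)
    terminus_sd: dict[str, float] = field(default_factory=_default_sd)
    ligatable_fraction: dict[str, float] = field(default_factory=_default_ligatable)
    gap_flap_len_mean: float = 4.0
    tf_sites: list[tuple[str, int, str]] = field(default_factory=_default_tf_sites)
    tf_barrier_weight: float = 0.8
    tf_halfwidth: int = 8
    ladder_weights: tuple[float, ...] = (0.7, 0.2, 0.1)
    min_fragment_length: int = 50
    decoupled_flap_mode: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be non-empty")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        if not self.origin_positions:
            raise ValueError("origin_positions must be non-empty")
        for chrom, pos in self.origin_positions:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"origin on unknown chromosome {chrom!r}")
            if not (0 <= pos < self.chrom_lengths[chrom]):
                raise ValueError(f"origin {chrom}:{pos} outside chromosome")
        if self.nucleosome_repeat < 100:
            raise ValueError("nucleosome_repeat must be >= 100 nt")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        for name, mapping in (
            ("terminus_shift", self.terminus_shift),
            ("terminus_sd", self.terminus_sd),
            ("ligatable_fraction", self.ligatable_fraction),
        ):
            for cond in CONDITIONS:
                if cond not in mapping:
                    raise ValueError(f"{name} missing condition {cond!r}")
                if not np.isfinite(mapping[cond]):
                    raise ValueError(f"{name}[{cond}] must be finite")
        for cond, frac in self.ligatable_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"ligatable_fraction[{cond}] must be in [0, 1]")
        for cond, sd in self.terminus_sd.items():
            if sd < 0:
                raise ValueError(f"terminus_sd[{cond}] must be >= 0")
        if not 0.0 <= self.tf_barrier_weight <= 1.0:
            raise ValueError("tf_barrier_weight must be in [0, 1]")
        for chrom, pos, orientation in self.tf_sites:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"TF site on unknown chromosome {chrom!r}")
            if not (0 <= pos < self.chrom_lengths[chrom]):
                raise ValueError(f"TF site {chrom}:{pos} outside chromosome")
            if orientation not in ("+", "-", "none"):
                raise ValueError("TF orientation must be +, - or none")
        if self.gap_flap_len_mean < 0:
            raise ValueError("gap_flap_len_mean must be >= 0")
        w = np.asarray(self.ladder_weights, dtype=float)
        if w.size < 1 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("ladder_weights must be non-negative and sum to 1")
        if self.min_fragment_length < 1:
            raise ValueError("min_fragment_length must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")


@dataclass
class GroundTruth:
    """Per-fragment generative truth, consistent with the emitted records.

    Offsets are signed and in synthesis orientation relative to the assigned
    dyad midpoint (positive = downstream of the dyad in synthesis direction).
    ``tf_relocated`` and ``edge_clipped`` mark fragments whose termini were
    moved by the TF-barrier rule or clipped at a chromosome boundary; the
    run-level summaries exclude those.
    """

    dyad_index: np.ndarray
    dyad_midpoint: np.ndarray
    strand_sign: np.ndarray
    offset3: np.ndarray
    offset5: np.ndarray
    junction_state: np.ndarray
    gap_or_flap_len: np.ndarray
    tf_relocated: np.ndarray
    edge_clipped: np.ndarray
    realized_shift: float
    realized_ligatable_fraction: float


class ForkDirectionMap:
    """Fork direction at every genomic position, from origin positions.

    Positions to the right of an origin are replicated by a rightward (``+``)
    fork and positions to the left by a leftward (``-``) fork; between two
    origins the boundary is their midpoint. A position exactly at an origin
    counts as rightward.
    """

    def __init__(self, origins_by_chrom: Mapping[str, Sequence[int]]):
        self._origins = {
            chrom: np.asarray(sorted(pos), dtype=np.int64)
            for chrom, pos in origins_by_chrom.items()
        }
        for chrom, pos in self._origins.items():
            if pos.size == 0:
                raise ValueError(f"chromosome {chrom} has no origin")

    def sign_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vector of +1/-1 fork-direction signs at ``positions``."""
        origins = self._origins[chrom]
        pos = np.asarray(positions, dtype=np.int64)
        if origins.size == 1:
            owner = np.zeros(pos.shape, dtype=np.int64)
        else:
            boundaries = (origins[:-1] + origins[1:]) // 2
            owner = np.searchsorted(boundaries, pos, side="right")
        return np.where(pos >= origins[owner], 1, -1).astype(np.int8)

    def at(self, chrom: str, position: int) -> str:
        """Fork direction '+' or '-' at a single position."""
        return "+" if self.sign_at(chrom, np.asarray([position]))[0] > 0 else "-"


def build_genome(config: SimulationConfig) -> tuple[FeatureSet, FeatureSet, ForkDirectionMap]:
    """Lay out dyads, TF sites and fork directions for a configuration.

    Dyads are tiled at ``repeat//2 + k*repeat`` (``length // repeat`` dyads
    per chromosome); occupancy scores are Gamma(2, 1) draws from the
    genome sub-stream of the seed, so the genome is shared by every
    condition simulated with the same seed.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _GENOME_STREAM])
    dyads: list[Feature] = []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        n = length // config.nucleosome_repeat
        mids = config.nucleosome_repeat // 2 + config.nucleosome_repeat * np.arange(n)
        scores = rng.gamma(2.0, 1.0, size=n)
        dyads.extend(
            Feature(chrom, int(m), float(s), "none") for m, s in zip(mids, scores)
        )
    tf = FeatureSet(
        kind="tf_site",
        records=tuple(
            Feature(chrom, pos, 1.0, orientation)
            for chrom, pos, orientation in sorted(config.tf_sites)
        ),
    )
    origins_by_chrom: dict[str, list[int]] = {}
    for chrom, pos in config.origin_positions:
        origins_by_chrom.setdefault(chrom, []).append(pos)
    for chrom in config.chrom_lengths:
        if chrom not in origins_by_chrom:
            raise ValueError(f"chromosome {chrom} has no replication origin")
    return (
        FeatureSet(kind="nucleosome_dyad", records=tuple(dyads)),
        tf,
        ForkDirectionMap(origins_by_chrom),
    )


def simulate_fragments(config: SimulationConfig) -> tuple[list[FragmentRecord], GroundTruth]:
    """Draw one fragment ensemble for ``config.condition``.

    Per fragment: a dyad is chosen uniformly; the local fork direction sets
    the strand; the 3' terminus is placed at the dyad plus the condition's
    signed shift and Gaussian noise (synthesis orientation); the 5' terminus
    is placed one fragment length upstream; junction states are drawn; and
    the TF hard-barrier rule may relocate the 3' terminus to the
    fork-proximal edge of a nearby site. All draws come from a condition-
    indexed sub-stream of the seed, so conditions share a genome but have
    independent, reproducible noise.
    """
    config.validate()
    if config.n_fragments <= 0:
        raise ValueError("n_fragments must be > 0")
    dyads, tf_sites, fork = build_genome(config)

    chroms = sorted(config.chrom_lengths)
    chrom_index = {c: i for i, c in enumerate(chroms)}
    chrom_len = np.asarray([config.chrom_lengths[c] for c in chroms], dtype=np.int64)

    d_chrom = np.asarray([chrom_index[f.chrom] for f in dyads], dtype=np.int64)
    d_mid = np.asarray([f.midpoint for f in dyads], dtype=np.int64)
    d_sign = np.empty(len(dyads), dtype=np.int8)
    for chrom in chroms:
        mask = d_chrom == chrom_index[chrom]
        d_sign[mask] = fork.sign_at(chrom, d_mid[mask])

    # Nearest TF site (same chromosome) per dyad, for the hard-barrier rule.
    d_tf_mid = np.full(len(dyads), -1, dtype=np.int64)
    d_tf_dist = np.full(len(dyads), np.iinfo(np.int64).max, dtype=np.int64)
    tf_by_chrom = tf_sites.by_chrom()
    for chrom, mids in tf_by_chrom.items():
        if chrom not in chrom_index:
            continue
        mask = d_chrom == chrom_index[chrom]
        pos = d_mid[mask]
        right = np.searchsorted(mids, pos)
        left = np.clip(right - 1, 0, mids.size - 1)
        right = np.clip(right, 0, mids.size - 1)
        dl = np.abs(pos - mids[left])
        dr = np.abs(mids[right] - pos)
        nearest = np.where(dr < dl, mids[right], mids[left])
        d_tf_mid[mask] = nearest
        d_tf_dist[mask] = np.abs(pos - nearest)

    cond = config.condition
    shift = config.terminus_shift[cond]
    sd = config.terminus_sd[cond]
    lig = config.ligatable_fraction[cond]
    n = config.n_fragments

    rng = np.random.default_rng([config.seed, _FRAGMENT_STREAM, CONDITIONS.index(cond)])
    di = rng.integers(0, len(dyads), size=n)
    k_nuc = rng.choice(
        np.arange(1, len(config.ladder_weights) + 1), size=n,
        p=np.asarray(config.ladder_weights, dtype=float),
    )
    length_noise = rng.normal(0.0, config.dyad_jitter_sd, size=n)
    terminus_noise = rng.normal(0.0, sd, size=n)
    tf_coin = rng.random(n)
    junction_coin = rng.random(n)
    gap_vs_flap = rng.integers(0, 2, size=n)  # 0 = gap, 1 = flap
    junction_len = 1 + rng.poisson(config.gap_flap_len_mean, size=n)

    m = d_mid[di]
    ci = d_chrom[di]
    s = d_sign[di].astype(np.int64)

    frag_len = np.rint(k_nuc * config.nucleosome_repeat + length_noise).astype(np.int64)
    frag_len = np.maximum(frag_len, config.min_fragment_length)

    if config.decoupled_flap_mode:
        # Strand-displacement scenario: 3' ends wild-type, 5' ends carry flaps.
        t3 = np.rint(m + s * terminus_noise).astype(np.int64)
        is_nick = np.zeros(n, dtype=bool)
        gap_vs_flap = np.ones(n, dtype=np.int64)
    else:
        t3 = np.rint(m + s * (shift + terminus_noise)).astype(np.int64)
        is_nick = junction_coin < lig

    tf_relocated = (tf_coin < config.tf_barrier_weight) & (
        d_tf_dist[di] <= config.nucleosome_repeat
    )
    if tf_relocated.any():
        t3 = np.where(tf_relocated, d_tf_mid[di] - s * config.tf_halfwidth, t3)

    t5 = t3 - s * (frag_len - 1)
    if config.decoupled_flap_mode:
        t5 = t5 - s * junction_len

    start = np.minimum(t3, t5)
    end = np.maximum(t3, t5) + 1
    cl = chrom_len[ci]
    edge_clipped = (start < 0) | (end > cl)
    start = np.clip(start, 0, None)
    end = np.minimum(end, cl)

    pos5 = np.where(s > 0, start, end - 1)
    pos3 = np.where(s > 0, end - 1, start)
    offset3 = s * (pos3 - m)
    offset5 = s * (pos5 - m)

    state = np.where(is_nick, "nick", np.where(gap_vs_flap == 0, "gap", "flap"))
    jlen = np.where(is_nick, 0, junction_len)

    records: list[FragmentRecord] = []
    for i in range(n):
        st = str(state[i])
        records.append(
            FragmentRecord(
                chrom=chroms[ci[i]],
                start=int(start[i]),
                end=int(end[i]),
                strand="+" if s[i] > 0 else "-",
                name=f"okf{i:06d}",
                score=0.0,
                junction_state=st,
                gap_or_flap_len=int(jlen[i]) if st != "nick" else None,
            )
        )

    clean = ~tf_relocated & ~edge_clipped
    realized_shift = float(offset3[clean].mean()) if clean.any() else float("nan")
    truth = GroundTruth(
        dyad_index=di,
        dyad_midpoint=m,
        strand_sign=s,
        offset3=offset3,
        offset5=offset5,
        junction_state=state,
        gap_or_flap_len=jlen,
        tf_relocated=tf_relocated,
        edge_clipped=edge_clipped,
        realized_shift=realized_shift,
        realized_ligatable_fraction=float(is_nick.mean()),
    )
    return records, truth


# ---------------------------------------------------------------------------
# Flat key=value serialization (configs and panel manifests)

def config_to_mapping(config: SimulationConfig) -> dict[str, str]:
    """Flatten a configuration to an ordered, round-trippable string map."""
    config.validate()
    out: dict[str, str] = {}
    out["chrom_lengths"] = ",".join(
        f"{c}:{config.chrom_lengths[c]}" for c in sorted(config.chrom_lengths)
    )
    out["origin_positions"] = ",".join(f"{c}:{p}" for c, p in config.origin_positions)
    out["nucleosome_repeat"] = str(config.nucleosome_repeat)
    out["dyad_jitter_sd"] = repr(config.dyad_jitter_sd)
    out["n_fragments"] = str(config.n_fragments)
    out["condition"] = config.condition
    for key, mapping in (
        ("terminus_shift", config.terminus_shift),
        ("terminus_sd", config.terminus_sd),
        ("ligatable_fraction", config.ligatable_fraction),
    ):
        out[key] = ",".join(f"{c}:{mapping[c]!r}" for c in CONDITIONS)
    out["gap_flap_len_mean"] = repr(config.gap_flap_len_mean)
    out["tf_sites"] = ",".join(f"{c}:{p}:{o}" for c, p, o in config.tf_sites)
    out["tf_barrier_weight"] = repr(config.tf_barrier_weight)
    out["tf_halfwidth"] = str(config.tf_halfwidth)
    out["ladder_weights"] = ",".join(repr(w) for w in config.ladder_weights)
    out["min_fragment_length"] = str(config.min_fragment_length)
    out["decoupled_flap_mode"] = "true" if config.decoupled_flap_mode else "false"
    out["seed"] = str(config.seed)
    return out


def config_from_mapping(mapping: Mapping[str, str]) -> SimulationConfig:
    """Inverse of :func:`config_to_mapping`."""

    def cond_map(raw: str) -> dict[str, float]:
        out = {}
        for tok in raw.split(","):
            cond, val = tok.rsplit(":", 1)
            out[cond] = float(val)
        return out

    chrom_lengths = {}
    for tok in mapping["chrom_lengths"].split(","):
        chrom, length = tok.rsplit(":", 1)
        chrom_lengths[chrom] = int(length)
    origins = []
    for tok in mapping["origin_positions"].split(","):
        chrom, pos = tok.rsplit(":", 1)
        origins.append((chrom, int(pos)))
    tf_sites = []
    if mapping.get("tf_sites", ""):
        for tok in mapping["tf_sites"].split(","):
            chrom, pos, orientation = tok.rsplit(":", 2)
            tf_sites.append((chrom, int(pos), orientation))
    config = SimulationConfig(
        chrom_lengths=chrom_lengths,
        origin_positions=origins,
        nucleosome_repeat=int(mapping["nucleosome_repeat"]),
        dyad_jitter_sd=float(mapping["dyad_jitter_sd"]),
        n_fragments=int(mapping["n_fragments"]),
        condition=mapping["condition"],
        terminus_shift=cond_map(mapping["terminus_shift"]),
        terminus_sd=cond_map(mapping["terminus_sd"]),
        ligatable_fraction=cond_map(mapping["ligatable_fraction"]),
        gap_flap_len_mean=float(mapping["gap_flap_len_mean"]),
        tf_sites=tf_sites,
        tf_barrier_weight=float(mapping["tf_barrier_weight"]),
        tf_halfwidth=int(mapping["tf_halfwidth"]),
        ladder_weights=tuple(float(w) for w in mapping["ladder_weights"].split(",")),
        min_fragment_length=int(mapping["min_fragment_length"]),
        decoupled_flap_mode=mapping["decoupled_flap_mode"] == "true",
        seed=int(mapping["seed"]),
    )
    config.validate()
    return config


def write_key_value(mapping: Mapping[str, str], path: str | Path, header: str = "") -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        if header:
            fh.write(f"# {header}\n")
        for key, value in mapping.items():
            fh.write(f"{key} = {value}\n")


def read_key_value(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_config(path: str | Path) -> SimulationConfig:
    return config_from_mapping(read_key_value(path))


def write_config(config: SimulationConfig, path: str | Path) -> None:
    write_key_value(config_to_mapping(config), path, header="okaseq simulation config")


def simulate_condition_panel(
    base_config: SimulationConfig,
    outdir: str | Path,
    conditions: Sequence[str] = CONDITIONS,
) -> dict[str, Path]:
    """Simulate one fragment file per condition over a shared genome.

    Writes ``dyads.bed`` and ``tf_sites.bed`` (identical for all conditions,
    by construction of the seed streams), one ``fragments_<condition>.bed``
    per requested condition, and a ``manifest.txt`` from which the whole
    panel can be reproduced byte-identically. Returns condition -> fragment
    file path.
    """
    base_config.validate()
    for cond in conditions:
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition {cond!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    dyads, tf_sites, _ = build_genome(base_config)
    write_features(dyads, outdir / "dyads.bed")
    write_features(tf_sites, outdir / "tf_sites.bed")

    paths: dict[str, Path] = {}
    for cond in conditions:
        config = replace(base_config, condition=cond)
        records, _ = simulate_fragments(config)
        path = outdir / f"fragments_{cond}.bed"
        write_fragments(records, path)
        paths[cond] = path

    manifest = dict(config_to_mapping(base_config))
    manifest["panel_conditions"] = ",".join(conditions)
    manifest["dyads_file"] = "dyads.bed"
    manifest["tf_sites_file"] = "tf_sites.bed"
    for cond in conditions:
        manifest[f"fragments_file.{cond}"] = paths[cond].name
    write_key_value(manifest, outdir / "manifest.txt", header="okaseq panel manifest")
    return paths
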