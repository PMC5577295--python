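"""Synthetic genus generator emulating a barcode study's data structure.

The generator produces a labelled, gap-free (by default) alignment for a
genus of many closely related species: a uniform-random ancestral sequence,
one founder per species evolved along a branch of expected length
``interspecific_depth`` (star phylogeny by default, mimicking a rapid
radiation), and a few haplotypes per species evolved from the founder along
branches of expected length ``intraspecific_theta / 2``. Samples are
assigned to haplotypes with the first haplotype weighted heaviest (the
dominant-haplotype pattern of real barcode data); with probability
``haplotype_sharing_prob`` a species replaces its last haplotype with a
verbatim copy of its sister species' dominant haplotype, which forces a
minimum interspecific distance of zero downstream.

Substitutions follow the Kimura 2-parameter process with
transition/transversion rate ratio ``kappa``: end states are drawn per site
from the exact finite-time K2P transition probabilities, with total rate
normalised so branch lengths are expected substitutions per site. Sharing
events are decided by per-species uniforms drawn from a dedicated stream,
so for a fixed seed the set of events is nested as the sharing probability
grows (common random numbers across probability series).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import (
    AlignedSequenceSet,
    collapse_haplotypes,
    write_alignment,
    write_haplotype_table,
)

__all__ = [
    "GenusSimulationConfig",
    "SharingEvent",
    "SyntheticGenus",
    "ConfigError",
    "simulate_genus",
    "make_fixture_suite",
    "table5_toy",
    "TABLE5_POSITIONS",
]

_DECODE = np.array(list("AGCT"))


class ConfigError(ValueError):
    """Invalid simulation configuration (caught before any sampling)."""


@dataclass(frozen=True)
class GenusSimulationConfig:
    """Full parameterization of the synthetic genus generator.

    ``samples_per_species`` is an inclusive ``(low, high)`` range, a single
    integer, or an explicit per-species list. ``interspecific_depth`` and
    ``intraspecific_theta`` are expected substitutions/site; with the
    default star phylogeny the expected distance between samples of two
    different species is ``2 * interspecific_depth + intraspecific_theta``
    and between different haplotypes of one species ``intraspecific_theta``.
    """

    n_species: int = 47
    samples_per_species: int | tuple[int, int] | tuple[int, ...] = (3, 6)
    sequence_length: int = 235
    interspecific_depth: float = 0.010
    intraspecific_theta: float = 0.008
    kappa: float = 2.0
    haplotype_sharing_prob: float = 0.0
    n_haplotypes_per_species: int = 3
    seed: int = 0
    tree_mode: str = "star"  # or "balanced"
    gap_injection_rate: float = 0.0
    force_sharing_species: tuple[int, ...] = ()

    def validate(self) -> None:
        if self.n_species < 1:
            raise ConfigError("n_species must be >= 1")
        if self.sequence_length < 1:
            raise ConfigError("sequence_length must be >= 1")
        if self.interspecific_depth < 0 or self.intraspecific_theta < 0:
            raise ConfigError("branch lengths must be >= 0")
        if self.kappa <= 0:
            raise ConfigError("kappa must be > 0")
        if not (0.0 <= self.haplotype_sharing_prob <= 1.0):
            raise ConfigError("haplotype_sharing_prob must be in [0, 1]")
        if not (0.0 <= self.gap_injection_rate <= 1.0):
            raise ConfigError("gap_injection_rate must be in [0, 1]")
        if self.n_haplotypes_per_species < 1:
            raise ConfigError("n_haplotypes_per_species must be >= 1")
        if self.tree_mode not in ("star", "balanced"):
            raise ConfigError(f"unknown tree_mode {self.tree_mode!r}")
        spp = self.samples_per_species
        if isinstance(spp, int):
            if spp < 1:
                raise ConfigError("samples_per_species must be >= 1")
        elif isinstance(spp, tuple) and len(spp) == 2:
            lo, hi = spp
            if not (1 <= lo <= hi):
                raise ConfigError(f"invalid samples_per_species range {spp}")
        elif isinstance(spp, (tuple, list)):
            if len(spp) != self.n_species or any(s < 1 for s in spp):
                raise ConfigError(
                    "per-species sample list must have n_species entries >= 1"
                )
        else:
            raise ConfigError(f"invalid samples_per_species {spp!r}")
        if any(not (0 <= i < self.n_species) for i in self.force_sharing_species):
            raise ConfigError("force_sharing_species indices out of range")


@dataclass(frozen=True)
class SharingEvent:
    species: str
    sister: str
    replaced_haplotype: str


@dataclass
class SyntheticGenus:
    """A simulated alignment plus the full generating truth."""

    alignment: AlignedSequenceSet
    species_map: dict[str, str]
    haplotype_assignments: dict[str, str]  # sample id -> true haplotype label
    sharing_events: list[SharingEvent]
    realized_substitutions: dict[str, int]  # branch label -> substituted sites
    config: GenusSimulationConfig = field(repr=False, default=None)  # type: ignore


def _k2p_site_probs(t: float, kappa: float) -> tuple[float, float, float]:
    """(p_same, p_transition, p_each_transversion) after branch length t."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return 1.0 - p_ts - 2.0 * p_tv, p_ts, p_tv


def _evolve(
    seq: np.ndarray, t: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve an encoded sequence along a branch of expected length t."""
    if t == 0.0:
        return seq.copy()
    p_same, p_ts, p_tv = _k2p_site_probs(t, kappa)
    u = rng.random(len(seq))
    out = seq.copy()
    # encoding A=0 G=1 C=2 T=3: transition partner is x^1, transversions x^2, x^3
    out[(u >= p_same) & (u < p_same + p_ts)] ^= 1
    out[(u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)] ^= 2
    out[u >= p_same + p_ts + p_tv] ^= 3
    return out


def _count_subs(parent: np.ndarray, child: np.ndarray) -> int:
    return int((parent != child).sum())


def _sample_sizes(
    cfg: GenusSimulationConfig, rng: np.random.Generator
) -> list[int]:
    spp = cfg.samples_per_species
    if isinstance(spp, int):
        return [spp] * cfg.n_species
    if isinstance(spp, tuple) and len(spp) == 2:
        lo, hi = spp
        return [int(x) for x in rng.integers(lo, hi + 1, size=cfg.n_species)]
    return [int(s) for s in spp]


def _founder_sequences(
    cfg: GenusSimulationConfig,
    ancestral: np.ndarray,
    rng: np.random.Generator,
    realized: dict[str, int],
    names: list[str],
) -> list[np.ndarray]:
    if cfg.tree_mode == "star":
        founders = []
        for name in names:
            f = _evolve(ancestral, cfg.interspecific_depth, cfg.kappa, rng)
            realized[f"founder:{name}"] = _count_subs(ancestral, f)
            founders.append(f)
        return founders
    # balanced mode: recursive bifurcation, per-level branch length chosen so
    # root-to-founder expectation stays ~ interspecific_depth
    levels = max(1, math.ceil(math.log2(cfg.n_species))) if cfg.n_species > 1 else 1
    step = cfg.interspecific_depth / levels

    def split(seq: np.ndarray, k: int) -> list[np.ndarray]:
        if k == 1:
            return [seq]
        left = _evolve(seq, step, cfg.kappa, rng)
        right = _evolve(seq, step, cfg.kappa, rng)
        half = (k + 1) // 2
        return split(left, half) + split(right, k - half)

    founders = split(ancestral, cfg.n_species)
    for name, f in zip(names, founders):
        realized[f"founder:{name}"] = _count_subs(ancestral, f)
    return founders


def simulate_genus(config: GenusSimulationConfig) -> SyntheticGenus:
    """Simulate a labelled genus alignment; fully reproducible from the config."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_anc, rng_founder, rng_hap, rng_sizes, rng_assign, rng_share, rng_gap = (
        np.random.default_rng(s) for s in ss.spawn(7)
    )

    L = config.sequence_length
    realized: dict[str, int] = {}
    species_names = [f"sp{i + 1:02d}" for i in range(config.n_species)]
    ancestral = rng_anc.integers(0, 4, size=L, dtype=np.int64)
    founders = _founder_sequences(config, ancestral, rng_founder, realized,
                                  species_names)
    sizes = _sample_sizes(config, rng_sizes)

    # haplotype sequences per species
    hap_branch = config.intraspecific_theta / 2.0
    hap_seqs: list[list[np.ndarray]] = []
    hap_labels: list[list[str]] = []
    for sp_i, name in enumerate(species_names):
        n_h = min(config.n_haplotypes_per_species, sizes[sp_i])
        seqs, labels = [], []
        for h in range(n_h):
            s = _evolve(founders[sp_i], hap_branch, config.kappa, rng_hap)
            label = f"{name}_h{h + 1}"
            realized[f"haplotype:{label}"] = _count_subs(founders[sp_i], s)
            seqs.append(s)
            labels.append(label)
        hap_seqs.append(seqs)
        hap_labels.append(labels)

    # sharing events: per-species uniforms from a dedicated stream so the
    # event set is nested in haplotype_sharing_prob for a fixed seed
    u = rng_share.random(config.n_species)
    sharing_events: list[SharingEvent] = []
    for sp_i, name in enumerate(species_names):
        sister = sp_i + 1 if sp_i % 2 == 0 else sp_i - 1
        if sister >= config.n_species:
            continue
        forced = sp_i in config.force_sharing_species
        if not forced and u[sp_i] >= config.haplotype_sharing_prob:
            continue
        replaced = len(hap_seqs[sp_i]) - 1
        hap_seqs[sp_i][replaced] = hap_seqs[sister][0].copy()
        sharing_events.append(
            SharingEvent(name, species_names[sister], hap_labels[sp_i][replaced])
        )

    # sample assignment: one sample per haplotype (coverage), then the first
    # two extras duplicate the dominant and the last haplotype (so shared
    # haplotypes carry >= 2 copies per species where sample sizes allow, the
    # tie structure seen in real shared-haplotype data), remaining extras
    # drawn with dominant-first weights 2^(n_h-1-k)
    records: list[tuple[str, str, str, str]] = []
    assignments: dict[str, str] = {}
    for sp_i, name in enumerate(species_names):
        n = sizes[sp_i]
        n_h = len(hap_seqs[sp_i])
        picks = list(range(n_h))
        if n > n_h:
            picks.append(0)
        if n > n_h + 1:
            picks.append(n_h - 1)
        weights = np.array([2.0 ** (n_h - 1 - k) for k in range(n_h)])
        weights /= weights.sum()
        if n > len(picks):
            picks += list(rng_assign.choice(n_h, size=n - len(picks), p=weights))
        for k, h in enumerate(picks):
            sid = f"{name}_{k + 1:03d}"
            residues = _DECODE[hap_seqs[sp_i][h]]
            if config.gap_injection_rate > 0:
                gaps = rng_gap.random(L) < config.gap_injection_rate
                residues = residues.copy()
                residues[gaps] = "-"
            population = f"{name}_pop{(k % 2) + 1}"
            records.append((sid, name, population, "".join(residues)))
            assignments[sid] = hap_labels[sp_i][h]

    aln = AlignedSequenceSet.from_records(records)
    return SyntheticGenus(
        alignment=aln,
        species_map=aln.species_map,
        haplotype_assignments=assignments,
        sharing_events=sharing_events,
        realized_substitutions=realized,
        config=config,
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

#: Published alignment positions of the three-column signature toy.
TABLE5_POSITIONS = (141, 152, 159)


def table5_toy() -> AlignedSequenceSet:
    """The printed three-site worked example: six 'CTC' target haplotype
    representatives plus 'TTC' and 'TTG' relatives (columns 1..3 stand for
    published positions 141/152/159)."""
    records = [(f"crenulata_{i}", "R_crenulata", "", "CTC") for i in range(1, 7)]
    records.append(("gelida_1", "R_gelida", "", "TTC"))
    records.append(("coccinea_1", "R_coccinea", "", "TTG"))
    return AlignedSequenceSet.from_records(records)


def _write_truth(genus: SyntheticGenus, out: Path) -> None:
    with open(out / "haplotype_truth.tsv", "w") as fh:
        fh.write("id\tspecies\ttrue_haplotype\n")
        for sid, hap in genus.haplotype_assignments.items():
            fh.write(f"{sid}\t{genus.species_map[sid]}\t{hap}\n")
    with open(out / "sharing_events.tsv", "w") as fh:
        fh.write("species\tsister\treplaced_haplotype\n")
        for ev in genus.sharing_events:
            fh.write(f"{ev.species}\t{ev.sister}\t{ev.replaced_haplotype}\n")
    with open(out / "realized_substitutions.tsv", "w") as fh:
        fh.write("branch\tn_substitutions\n")
        for branch, n in genus.realized_substitutions.items():
            fh.write(f"{branch}\t{n}\n")
    with open(out / "config.txt", "w") as fh:
        for k, v in asdict(genus.config).items():
            fh.write(f"{k} = {v!r}\n")


def _write_genus(genus: SyntheticGenus, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_alignment(genus.alignment, out / "alignment.fasta", out / "samples.tsv")
    _write_truth(genus, out)


def make_fixture_suite(out_dir: str | Path, seed: int) -> dict[str, Path]:
    """Write the standard fixture family used by the tests and docs.

    ``table5`` — the printed three-site toy with its column/position map;
    ``shared6`` — a 6-species genus with one forced shared-haplotype pair;
    ``genus47`` — a 47-species genus at the study's divergence magnitudes.
    Returns the fixture directories.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    t5 = out_dir / "table5"
    t5.mkdir(exist_ok=True)
    toy = table5_toy()
    write_alignment(toy, t5 / "alignment.fasta", t5 / "samples.tsv")
    with open(t5 / "colmap.tsv", "w") as fh:
        fh.write("aligned_column\tpublished_position\n")
        for c, p in enumerate(TABLE5_POSITIONS, start=1):
            fh.write(f"{c}\t{p}\n")
    write_haplotype_table(collapse_haplotypes(toy), t5 / "haplotypes.tsv")
    paths["table5"] = t5

    shared = simulate_genus(
        GenusSimulationConfig(
            n_species=6,
            samples_per_species=5,
            seed=seed,
            haplotype_sharing_prob=0.0,
            force_sharing_species=(1,),
        )
    )
    _write_genus(shared, out_dir / "shared6")
    paths["shared6"] = out_dir / "shared6"

    genus47 = simulate_genus(
        GenusSimulationConfig(
            n_species=47, seed=seed + 1, haplotype_sharing_prob=0.1
        )
    )
    _write_genus(genus47, out_dir / "genus47")
    paths["genus47"] = out_dir / "genus47"
    return paths
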