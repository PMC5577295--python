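"""Best-hit and nearest-distance species identification with three-way outcomes.

Each query sequence is compared against every other sequence in the data
set (the query itself is excluded — the reference database here is the data
set itself, as in barcode-library self-tests). Two rules are provided:

* ``best_hit`` — a BLAST-style surrogate that scores every query/reference
  pair by the number of identical non-gap aligned columns and takes all
  co-optimal references as hits;
* ``nearest_distance`` — the reference(s) at the smallest defined K2P
  distance are the hits.

The outcome is CORRECT when the hits come only from the query's species,
AMBIGUOUS when several species including the query's are co-optimal, and
INCORRECT when the query's species is absent from the hits. Species-level
tabulation assigns each species the worst outcome among its queries
(INCORRECT > AMBIGUOUS > CORRECT) and reports percentages over species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .core_io import AlignedSequenceSet
from .distances import DistanceMatrix, distance_matrix

__all__ = [
    "CORRECT",
    "AMBIGUOUS",
    "INCORRECT",
    "QueryOutcome",
    "SpeciesTabulation",
    "IdentificationError",
    "TabulationError",
    "nearest_distance_identify",
    "best_hit_identify",
    "identify_all",
    "tabulate_species",
    "write_outcomes_tsv",
    "write_tabulation_tsv",
]

logger = logging.getLogger(__name__)

CORRECT = "CORRECT"
AMBIGUOUS = "AMBIGUOUS"
INCORRECT = "INCORRECT"


class IdentificationError(ValueError):
    """No usable reference for a query (e.g. all distances undefined)."""


class TabulationError(ValueError):
    """Species-level tabulation impossible (species with zero queries)."""


@dataclass(frozen=True)
class QueryOutcome:
    query_id: str
    true_species: str
    method: Literal["best_hit", "nearest_distance"]
    outcome: Literal["CORRECT", "AMBIGUOUS", "INCORRECT"]
    hit_species: frozenset[str]
    optimum_value: float


def _classify(true_species: str, hit_species: frozenset[str]) -> str:
    if hit_species == {true_species}:
        return CORRECT
    if true_species in hit_species:
        return AMBIGUOUS
    return INCORRECT


def nearest_distance_identify(
    query_id: str,
    dm: DistanceMatrix,
    species_map: Mapping[str, str],
    leave_one_out: bool = True,
) -> QueryOutcome:
    """Identify one query by the smallest defined pairwise distance.

    With ``leave_one_out`` (default) the query itself is excluded from the
    candidate references; identical conspecific sequences legitimately
    remain. Candidates whose distance to the query is undefined are dropped
    with a warning. All references attaining the minimal distance contribute
    their species to the hit set.
    """
    qi = dm.index_of(query_id)
    true_species = species_map[query_id]
    best = math.inf
    hits: set[str] = set()
    n_undefined = 0
    for j, lbl in enumerate(dm.labels):
        if leave_one_out and j == qi:
            continue
        # without leave-one-out the query matches itself at distance 0
        v = dm.values[qi, j] if j != qi else 0.0
        if math.isnan(v):
            n_undefined += 1
            continue
        if v < best - 1e-15:
            best = v
            hits = {species_map[lbl]}
        elif abs(v - best) <= 1e-15:
            hits.add(species_map[lbl])
    if n_undefined:
        logger.warning(
            "query %s: %d candidates with undefined distance excluded",
            query_id, n_undefined,
        )
    if not hits:
        raise IdentificationError(
            f"query {query_id!r}: no reference with a defined distance"
        )
    return QueryOutcome(
        query_id, true_species, "nearest_distance",
        _classify(true_species, frozenset(hits)), frozenset(hits), best,
    )


def _identity_scores(aln: AlignedSequenceSet) -> np.ndarray:
    """Pairwise counts of identical non-gap aligned columns (BLAST surrogate)."""
    chars = np.array(
        [list(r.residues) for r in aln.records], dtype="U1"
    )
    n = chars.shape[0]
    scores = np.zeros((n, n), dtype=int)
    nongap = chars != "-"
    for i in range(n):
        eq = (chars == chars[i]) & nongap & nongap[i]
        scores[i] = eq.sum(axis=1)
    return scores


def best_hit_identify(
    query_id: str,
    aln: AlignedSequenceSet,
    species_map: Mapping[str, str] | None = None,
    _scores: np.ndarray | None = None,
) -> QueryOutcome:
    """Identify one query by maximal aligned-column identity (best hit).

    All references sharing the top identity score contribute their species;
    the query itself is never a candidate. ``_scores`` allows a precomputed
    score matrix to be reused across queries.
    """
    if species_map is None:
        species_map = aln.species_map
    ids = aln.ids
    qi = ids.index(query_id)
    scores = _scores if _scores is not None else _identity_scores(aln)
    row = scores[qi]
    best = -1
    hits: set[str] = set()
    for j, lbl in enumerate(ids):
        if j == qi:
            continue
        s = int(row[j])
        if s > best:
            best = s
            hits = {species_map[lbl]}
        elif s == best:
            hits.add(species_map[lbl])
    if not hits:
        raise IdentificationError(f"query {query_id!r}: no candidate references")
    true_species = species_map[query_id]
    return QueryOutcome(
        query_id, true_species, "best_hit",
        _classify(true_species, frozenset(hits)), frozenset(hits), float(best),
    )


def identify_all(
    aln: AlignedSequenceSet,
    method: Literal["best_hit", "nearest_distance"],
    dm: DistanceMatrix | None = None,
) -> list[QueryOutcome]:
    """Run one identification method with every sequence as a query."""
    species_map = aln.species_map
    if method == "nearest_distance":
        if dm is None:
            dm = distance_matrix(aln)
        return [
            nearest_distance_identify(q, dm, species_map) for q in aln.ids
        ]
    if method == "best_hit":
        scores = _identity_scores(aln)
        return [
            best_hit_identify(q, aln, species_map, _scores=scores)
            for q in aln.ids
        ]
    raise ValueError(f"unknown identification method {method!r}")


@dataclass
class SpeciesTabulation:
    """Per-species outcomes and counts/percentages over species."""

    per_species: dict[str, str]
    n_samples: int
    n_species: int
    n_correct: int
    n_incorrect: int
    n_ambiguous: int

    @property
    def pct_correct(self) -> float:
        return 100.0 * self.n_correct / self.n_species

    @property
    def pct_incorrect(self) -> float:
        return 100.0 * self.n_incorrect / self.n_species

    @property
    def pct_ambiguous(self) -> float:
        return 100.0 * self.n_ambiguous / self.n_species


def tabulate_species(
    outcomes: Sequence[QueryOutcome],
    species_map: Mapping[str, str],
) -> SpeciesTabulation:
    """Collapse per-query outcomes to a species-level table.

    A species is INCORRECT if any of its queries is INCORRECT, else
    AMBIGUOUS if any query is AMBIGUOUS, else CORRECT. Percentages are over
    species, not queries. Every species in ``species_map`` must have at
    least one query outcome.
    """
    per_species: dict[str, str] = {}
    queried: dict[str, list[str]] = {}
    for o in outcomes:
        queried.setdefault(o.true_species, []).append(o.outcome)
    all_species = sorted(set(species_map.values()))
    empty = [sp for sp in all_species if sp not in queried]
    if empty:
        raise TabulationError(f"species with zero query outcomes: {empty[:5]}")
    for sp in all_species:
        outs = queried[sp]
        if INCORRECT in outs:
            per_species[sp] = INCORRECT
        elif AMBIGUOUS in outs:
            per_species[sp] = AMBIGUOUS
        else:
            per_species[sp] = CORRECT
    vals = list(per_species.values())
    return SpeciesTabulation(
        per_species=per_species,
        n_samples=len(outcomes),
        n_species=len(all_species),
        n_correct=vals.count(CORRECT),
        n_incorrect=vals.count(INCORRECT),
        n_ambiguous=vals.count(AMBIGUOUS),
    )


def write_outcomes_tsv(outcomes: Sequence[QueryOutcome], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\ttrue_species\tmethod\toutcome\thit_species\toptimum\n")
        for o in outcomes:
            fh.write(
                f"{o.query_id}\t{o.true_species}\t{o.method}\t{o.outcome}\t"
                f"{','.join(sorted(o.hit_species))}\t{o.optimum_value:.6g}\n"
            )


def write_tabulation_tsv(
    tab: SpeciesTabulation, path: str | Path, marker: str = "", method: str = ""
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "marker\tmethod\tn_samples\tn_species\tcorrect\tincorrect\tambiguous\n"
        )
        fh.write(
            f"{marker}\t{method}\t{tab.n_samples}\t{tab.n_species}\t"
            f"{tab.n_correct} ({tab.pct_correct:.1f}%)\t"
            f"{tab.n_incorrect} ({tab.pct_incorrect:.1f}%)\t"
            f"{tab.n_ambiguous} ({tab.pct_ambiguous:.1f}%)\n"
        )
        fh.write("\nspecies\toutcome\n")
        for sp, out in tab.per_species.items():
            fh.write(f"{sp}\t{out}\n")
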