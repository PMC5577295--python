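"""Diagnostic ("stable") SNP sites and minimal multi-site nucleotide signatures.

A single-site diagnostic for a target species is an alignment column at
which every target member carries the same unambiguous base and no other
sequence can carry that base. A multi-site signature is a set of columns
whose joint target state vector occurs in every target member and in no
other sequence; only minimal such sets are reported (removing any column
breaks uniqueness).

Conservatively, a gap or ambiguity code in a *non-target* sequence at a
candidate column is treated as possibly matching: a signature must not
misfire on incomplete data. Columns where any *target* member has a gap or
ambiguity, or where the target is not fixed, are never candidates.

Positions are reported 1-based relative to the analysed alignment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .core_io import AlignedSequenceSet, PURE_BASES

__all__ = [
    "SingleSiteDiagnostic",
    "SignatureCombination",
    "DiagnosticReport",
    "DiagnosticsSearchError",
    "find_diagnostic_sites",
    "find_minimal_combinations",
    "write_diagnostics_tsv",
    "write_state_matrix_tsv",
]


class DiagnosticsSearchError(ValueError):
    """Combinatorial search would exceed the configured ceiling."""


@dataclass(frozen=True)
class SingleSiteDiagnostic:
    position: int  # 1-based
    target_state: str
    other_states: frozenset[str]


@dataclass(frozen=True)
class SignatureCombination:
    positions: tuple[int, ...]  # 1-based, ascending
    target_states: str


@dataclass
class DiagnosticReport:
    target_species: str
    single_site_diagnostics: list[SingleSiteDiagnostic] = field(default_factory=list)
    minimal_combinations: list[SignatureCombination] = field(default_factory=list)
    max_combination_size: int = 0
    alignment_name: str = ""

    @property
    def found(self) -> bool:
        return bool(self.single_site_diagnostics or self.minimal_combinations)


def _split_members(
    aln: AlignedSequenceSet, target: str, group_map: Mapping[str, str] | None
):
    group_map = group_map if group_map is not None else aln.species_map
    target_rows = [r.residues for r in aln.records if group_map[r.id] == target]
    other_rows = [r.residues for r in aln.records if group_map[r.id] != target]
    if not target_rows:
        raise KeyError(f"no sequences labelled {target!r}")
    return target_rows, other_rows


def _fixed_columns(
    target_rows: list[str], length: int
) -> dict[int, str]:
    """0-based columns where all target members share one unambiguous base."""
    fixed: dict[int, str] = {}
    for c in range(length):
        states = {row[c] for row in target_rows}
        if len(states) == 1:
            (state,) = states
            if state in PURE_BASES:
                fixed[c] = state
    return fixed


def _possibly_matches(row: str, columns: tuple[int, ...], states: str) -> bool:
    """Non-target row compatible with the signature (gap/ambiguity = possible)."""
    for c, s in zip(columns, states):
        ch = row[c]
        if ch in PURE_BASES and ch != s:
            return False
    return True


def find_diagnostic_sites(
    aln: AlignedSequenceSet,
    target: str,
    group_map: Mapping[str, str] | None = None,
) -> DiagnosticReport:
    """Scan every column for single-site diagnostics of ``target``.

    ``group_map`` defaults to the species map; passing the population map
    turns the same scan into a population-specific (geographic) search.
    """
    target_rows, other_rows = _split_members(aln, target, group_map)
    report = DiagnosticReport(target_species=target)
    for c, state in sorted(_fixed_columns(target_rows, aln.alignment_length).items()):
        if any(_possibly_matches(row, (c,), state) for row in other_rows):
            continue
        others = frozenset(row[c] for row in other_rows)
        report.single_site_diagnostics.append(
            SingleSiteDiagnostic(c + 1, state, others)
        )
    return report


def find_minimal_combinations(
    aln: AlignedSequenceSet,
    target: str,
    max_k: int = 3,
    group_map: Mapping[str, str] | None = None,
    search_ceiling: int = 200_000,
) -> DiagnosticReport:
    """Exhaustive search for minimal diagnostic column combinations.

    Candidate columns are those fixed (unambiguous) within the target.
    Subsets are examined in (size, lexicographic) order up to ``max_k``
    columns; a subset is reported when no non-target sequence can match its
    joint state vector and no reported subset is contained in it. Refuses
    to run when the number of subsets to examine exceeds ``search_ceiling``.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    target_rows, other_rows = _split_members(aln, target, group_map)
    fixed = _fixed_columns(target_rows, aln.alignment_length)
    # a combination excludes a non-target row iff some column shows a hard
    # (unambiguous) mismatch; columns excluding nobody can never be part of a
    # minimal combination, so only columns with >= 1 hard mismatch remain
    excluded_by: dict[int, frozenset[int]] = {}
    for c, state in fixed.items():
        excl = frozenset(
            i for i, row in enumerate(other_rows)
            if row[c] in PURE_BASES and row[c] != state
        )
        if excl:
            excluded_by[c] = excl
    cols = sorted(excluded_by)
    everyone = frozenset(range(len(other_rows)))
    n_subsets = sum(math.comb(len(cols), k) for k in range(1, max_k + 1))
    if n_subsets > search_ceiling:
        raise DiagnosticsSearchError(
            f"{n_subsets} candidate subsets exceed the ceiling {search_ceiling}; "
            "lower max_k or raise search_ceiling"
        )
    report = DiagnosticReport(target_species=target, max_combination_size=max_k)
    found: list[tuple[int, ...]] = []
    for k in range(1, max_k + 1):
        for combo in itertools.combinations(cols, k):
            if any(set(f).issubset(combo) for f in found):
                continue  # a strict subset already diagnostic: not minimal
            covered = frozenset().union(*(excluded_by[c] for c in combo))
            if covered != everyone:
                continue
            found.append(combo)
            report.minimal_combinations.append(
                SignatureCombination(
                    tuple(c + 1 for c in combo),
                    "".join(fixed[c] for c in combo),
                )
            )
    # mirror the single-site scan in the same report
    report.single_site_diagnostics = find_diagnostic_sites(
        aln, target, group_map
    ).single_site_diagnostics
    return report


def write_diagnostics_tsv(report: DiagnosticReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#target_species\t{report.target_species}\n")
        if report.alignment_name:
            fh.write(f"#alignment\t{report.alignment_name}\n")
        fh.write("type\tpositions\ttarget_states\tother_states\n")
        for s in report.single_site_diagnostics:
            fh.write(
                f"single_site\t{s.position}\t{s.target_state}\t"
                f"{','.join(sorted(s.other_states))}\n"
            )
        for c in report.minimal_combinations:
            fh.write(
                "combination\t"
                + ",".join(map(str, c.positions))
                + f"\t{c.target_states}\t\n"
            )
        if not report.found:
            fh.write("none_found\t\t\t\n")


def write_state_matrix_tsv(
    aln: AlignedSequenceSet,
    positions: list[int],
    path: str | Path,
) -> None:
    """Dump per-sequence states at the given 1-based positions (signature view)."""
    with open(path, "w") as fh:
        fh.write("id\tspecies\t" + "\t".join(f"pos_{p}" for p in positions) + "\n")
        for r in aln.records:
            states = "\t".join(r.residues[p - 1] for p in positions)
            fh.write(f"{r.id}\t{r.species}\t{states}\n")
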