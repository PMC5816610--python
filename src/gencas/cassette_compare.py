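"""Functional-content comparison of cassettes.

Two genes are compatible when their label sets share a function label (with
priority ec3 > cog > role when several are shared).  The match size between
two cassettes is the cardinality of a maximum one-to-one matching on the
gene-compatibility graph, so a cassette with two transporters can only match
two transporter genes on the other side, never one gene twice.

A cassette database can then be searched for *conserved function
combinations*: label multisets realised by cassettes in multiple taxonomic
groups, evidence for a shared pathway.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from gencas.cassette_assembly import Cassette
from gencas.fingerprint import FunctionLabel

_KIND_PRIORITY = {"ec3": 0, "cog": 1, "role": 2}


@dataclass(frozen=True)
class CassetteMatch:
    """One-to-one pairing of genes between two cassettes by shared function."""

    cassette_a: str
    cassette_b: str
    pairs: tuple[tuple[int, int, FunctionLabel], ...]
    match_size: int
    matched_combination: tuple[FunctionLabel, ...]  # sorted multiset


@dataclass(frozen=True)
class ConservedCombination:
    """A function-label multiset covered by cassettes of several taxon groups."""

    combination: tuple[FunctionLabel, ...]  # sorted multiset
    supporting: tuple[tuple[str, str, str], ...]  # (species, taxon_group, cassette_id)
    group_count: int


def gene_compatible(
    labels_a: Iterable[FunctionLabel], labels_b: Iterable[FunctionLabel]
) -> FunctionLabel | None:
    """Shared label of two genes, or None when the label sets are disjoint.

    When several labels are shared the most specific kind wins (ec3 > cog >
    role); within a kind the lexicographically smallest value, for
    determinism.
    """
    shared = set(labels_a) & set(labels_b)
    if not shared:
        return None
    return min(shared, key=lambda l: (_KIND_PRIORITY[l.kind], l.value))


def _max_matching(adjacency: Sequence[Sequence[int]], n_right: int) -> list[int]:
    """Maximum bipartite matching by ordered augmenting paths (Kuhn's).

    ``adjacency[i]`` lists right-side partners of left node ``i`` in
    preference order.  Left nodes are processed in index order and each
    augmenting search scans partners in listed order, so the result is
    deterministic and prefers low left indices, then low right indices.
    Returns ``match_right`` where ``match_right[j]`` is the left partner of
    right node ``j`` or -1.
    """
    match_right = [-1] * n_right

    def try_augment(i: int, visited: list[bool]) -> bool:
        for j in adjacency[i]:
            if visited[j]:
                continue
            visited[j] = True
            if match_right[j] == -1 or try_augment(match_right[j], visited):
                match_right[j] = i
                return True
        return False

    for i in range(len(adjacency)):
        try_augment(i, [False] * n_right)
    return match_right


def match_cassettes(a: Cassette, b: Cassette) -> CassetteMatch:
    """Maximum one-to-one functional match between two cassettes."""
    la, lb = a.fingerprint.gene_labels, b.fingerprint.gene_labels
    shared: dict[tuple[int, int], FunctionLabel] = {}
    adjacency: list[list[int]] = []
    for i in range(len(la)):
        row = []
        for j in range(len(lb)):
            lab = gene_compatible(la[i], lb[j])
            if lab is not None:
                shared[(i, j)] = lab
                row.append(j)
        adjacency.append(row)
    match_right = _max_matching(adjacency, len(lb))
    pairs = sorted(
        (i, j, shared[(i, j)]) for j, i in enumerate(match_right) if i != -1
    )
    combination = tuple(sorted(lab for _, _, lab in pairs))
    return CassetteMatch(
        cassette_a=a.cassette_id,
        cassette_b=b.cassette_id,
        pairs=tuple(pairs),
        match_size=len(pairs),
        matched_combination=combination,
    )


def covers_combination(cassette: Cassette, combination: Sequence[FunctionLabel]) -> bool:
    """Whether a cassette admits a one-to-one assignment of its genes to the
    combination's label instances (each gene used at most once)."""
    labels = cassette.fingerprint.gene_labels
    adjacency = [
        [j for j, gene_labels in enumerate(labels) if lab in gene_labels]
        for lab in combination
    ]
    match_right = _max_matching(adjacency, len(labels))
    return sum(1 for i in match_right if i != -1) == len(combination)


def search_conserved_combinations(
    db: Sequence[Cassette], min_size: int = 4, min_groups: int = 2
) -> list[ConservedCombination]:
    """All maximal function combinations conserved across taxonomic groups.

    Candidate combinations are generated by intersecting observed cassette
    fingerprints (the matched combination of every cassette pair), never by
    enumerating a blind powerset.  A combination is reported when cassettes
    from at least ``min_groups`` distinct taxon groups cover it and it is not
    a sub-multiset of another reported combination.

    Output sorted by (size desc, group_count desc, lexicographic).
    """
    if min_size < 1 or min_groups < 1:
        raise ValueError("min_size and min_groups must be >= 1")
    db = list(db)
    candidates: set[tuple[FunctionLabel, ...]] = set()
    for i in range(len(db)):
        for j in range(i + 1, len(db)):
            combo = match_cassettes(db[i], db[j]).matched_combination
            if len(combo) >= min_size:
                candidates.add(combo)

    results: list[ConservedCombination] = []
    for combo in candidates:
        supporting = tuple(
            (c.species, c.taxon_group, c.cassette_id)
            for c in db
            if covers_combination(c, combo)
        )
        groups = {s[1] for s in supporting}
        if len(groups) >= min_groups:
            results.append(
                ConservedCombination(
                    combination=combo,
                    supporting=supporting,
                    group_count=len(groups),
                )
            )

    # keep only maximal multisets
    counters = {r.combination: Counter(r.combination) for r in results}
    maximal = []
    for r in results:
        c = counters[r.combination]
        is_sub = any(
            other.combination != r.combination
            and len(other.combination) >= len(r.combination)
            and all(counters[other.combination][k] >= v for k, v in c.items())
            for other in results
        )
        if not is_sub:
            maximal.append(r)
    maximal.sort(
        key=lambda r: (
            -len(r.combination),
            -r.group_count,
            tuple(str(l) for l in r.combination),
        )
    )
    return maximal


def match_to_frame(match: CassetteMatch, a: Cassette, b: Cassette):
    """Pairing table for one cassette match."""
    import pandas as pd

    rows = [
        {
            "gene_a": a.genes[i].gene_id,
            "gene_b": b.genes[j].gene_id,
            "shared_label": str(lab),
        }
        for i, j, lab in match.pairs
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "shared_label"])


def combinations_to_frame(combos: Sequence[ConservedCombination]):
    import pandas as pd

    rows = [
        {
            "size": len(c.combination),
            "group_count": c.group_count,
            "combination": ",".join(str(l) for l in c.combination),
            "supporting_cassettes": ";".join(f"{s[0]}|{s[1]}|{s[2]}" for s in c.supporting),
        }
        for c in combos
    ]
    return pd.DataFrame(
        rows, columns=["size", "group_count", "combination", "supporting_cassettes"]
    )
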