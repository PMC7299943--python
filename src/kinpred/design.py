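"""Discovery/target study designs with controlled relatedness.

Mirrors the two experimental layouts used throughout the analysis:

* **large-scale**: prune to a pool with all pairwise genomic relationships
  below a threshold (default 0.05), split 80/20 into discovery and target,
  then substitute a fixed number of individuals by relatives of a given
  degree;
* **small-scale**: build the undirected graph linking degree-d relatives,
  take whole family components greedily from the largest down until the
  requested sample size is reached, then split into discovery and target
  (optionally forcing every target to have — or to lack — a degree-matched
  relative inside discovery: the TA/TB variants).
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd

from .relmat import KinshipEstimate, RelationshipMatrix


class DesignError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class StudyDesign:
    """Disjoint discovery/target id sets tagged with relatedness degree."""

    discovery_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    degree_label: str = "unrelated"  # {unrelated, 1, 2, 3}
    scale_label: str = "small"       # {large, small}
    seed: int = 0

    def __post_init__(self) -> None:
        disc, targ = set(self.discovery_ids), set(self.target_ids)
        if len(disc) != len(self.discovery_ids) or len(targ) != len(self.target_ids):
            raise DesignError("duplicated ids within a role")
        if disc & targ:
            raise DesignError(
                f"discovery and target overlap: {sorted(disc & targ)[:5]}"
            )

    @property
    def all_ids(self) -> tuple[str, ...]:
        return self.discovery_ids + self.target_ids

    def write_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("IID\trole\n")
            for i in self.discovery_ids:
                fh.write(f"{i}\tdiscovery\n")
            for i in self.target_ids:
                fh.write(f"{i}\ttarget\n")

    @classmethod
    def read_tsv(cls, path, **labels) -> "StudyDesign":
        tab = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        return cls(
            tuple(tab.loc[tab["role"] == "discovery", "IID"]),
            tuple(tab.loc[tab["role"] == "target", "IID"]),
            **labels,
        )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _pairs_above(source, threshold: float) -> tuple[list[tuple[str, str]], list[str]]:
    """(violating pairs, universe of ids) from a RelationshipMatrix or a
    KinshipEstimate list."""
    if isinstance(source, RelationshipMatrix):
        ids = list(source.ids)
        iu, ju = np.where(np.triu(source.values, k=1) > threshold)
        pairs = [(ids[i], ids[j]) for i, j in zip(iu, ju)]
        return pairs, ids
    pairs, ids = [], []
    seen = set()
    for est in source:
        for v in (est.id_i, est.id_j):
            if v not in seen:
                seen.add(v)
                ids.append(v)
        if est.phi > threshold:
            pairs.append((est.id_i, est.id_j))
    return pairs, ids


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def prune_unrelated(source, threshold: float = 0.05, seed: int = 0) -> set[str]:
    """Iteratively remove one random member of any pair related above the
    threshold, until no violating pair remains.

    ``source`` is a RelationshipMatrix (off-diagonals compared to the
    threshold) or a list of KinshipEstimate (phi compared).  Pair-at-a-time
    random removal, not a maximum independent set.
    """
    if threshold <= 0:
        raise DesignError("threshold must be > 0")
    pairs, ids = _pairs_above(source, threshold)
    retained = set(ids)
    rng = np.random.default_rng(seed)
    active = sorted(pairs)
    while True:
        active = [(a, b) for a, b in active if a in retained and b in retained]
        if not active:
            break
        a, b = active[rng.integers(len(active))]
        retained.discard((a, b)[rng.integers(2)])
    # post-condition: no retained pair exceeds the threshold
    assert not [(a, b) for a, b in pairs if a in retained and b in retained]
    return retained


def build_family_graph(pairs: list[KinshipEstimate], degree) -> list[nx.Graph]:
    """Connected components of the graph whose edges are exactly the
    degree-``degree`` pairs, sorted by decreasing size (ties: lexicographic
    smallest member id)."""
    want = str(degree)
    if want not in ("1", "2", "3"):
        raise DesignError("degree must be 1, 2 or 3")
    g = nx.Graph()
    g.add_edges_from(
        (est.id_i, est.id_j) for est in pairs if est.degree == want
    )
    comps = [g.subgraph(c).copy() for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c.nodes)))
    return comps


def select_related_subset(components: list[nx.Graph], n_total: int) -> set[str]:
    """Whole components greedily in decreasing size order until ``n_total``
    is reached; the component that overflows is truncated keeping its
    highest-graph-degree members first (ties by id)."""
    avail = sum(len(c) for c in components)
    if n_total > avail:
        raise DesignError(
            f"requested {n_total} individuals but components hold only {avail} "
            f"(shortfall {n_total - avail})"
        )
    chosen: set[str] = set()
    for comp in components:
        need = n_total - len(chosen)
        if need <= 0:
            break
        if len(comp) <= need:
            chosen.update(comp.nodes)
        else:
            ranked = sorted(comp.nodes, key=lambda v: (-comp.degree(v), v))
            chosen.update(ranked[:need])
            break
    return chosen


def substitute_relatives(base: StudyDesign, relatives, seed: int = 0) -> StudyDesign:
    """Replace a seeded random subset of the base design by the given
    relatives, keeping the discovery and target sizes identical.

    Relatives already present in the base stay where they are; the remainder
    replace randomly chosen members, entering discovery or target according
    to where the replaced members sat (so the split fractions are preserved).
    """
    base_all = set(base.all_ids)
    incoming = sorted(set(relatives) - base_all)
    k = len(incoming)
    if k > len(base_all):
        raise DesignError(
            f"{k} relatives exceed the design size {len(base_all)}"
        )
    if k == 0:
        return base
    rng = np.random.default_rng(seed)
    removed = set(rng.choice(sorted(base_all), size=k, replace=False).tolist())
    k_disc = len(removed & set(base.discovery_ids))
    incoming = list(incoming)
    rng.shuffle(incoming)
    disc = [i for i in base.discovery_ids if i not in removed] + incoming[:k_disc]
    targ = [i for i in base.target_ids if i not in removed] + incoming[k_disc:]
    return StudyDesign(
        tuple(disc), tuple(targ), base.degree_label, base.scale_label, seed
    )


def split_design(
    ids,
    discovery_fraction: float,
    seed: int = 0,
    pairs: list[KinshipEstimate] | None = None,
    related_targets: bool | None = None,
    degree_label: str = "unrelated",
    scale_label: str = "small",
) -> StudyDesign:
    """Seeded random discovery/target split.

    With ``related_targets=True`` (the TA variant) every target is required
    to have at least one partner from ``pairs`` inside discovery; with
    ``related_targets=False`` (TB) targets are drawn among individuals with
    no partner in the pool at all.  ``pairs`` should already be filtered to
    the degree of interest.
    """
    if not 0.0 < discovery_fraction < 1.0:
        raise DesignError("discovery_fraction must be in (0, 1)")
    pool = sorted(set(ids))
    n = len(pool)
    if n < 2:
        raise DesignError("need at least 2 ids to split")
    n_disc = min(max(int(round(discovery_fraction * n)), 1), n - 1)
    n_targ = n - n_disc
    rng = np.random.default_rng(seed)
    order = list(pool)
    rng.shuffle(order)

    if related_targets is None:
        disc, targ = order[:n_disc], order[n_disc:]
    else:
        partners: dict[str, set[str]] = {}
        for est in pairs or []:
            partners.setdefault(est.id_i, set()).add(est.id_j)
            partners.setdefault(est.id_j, set()).add(est.id_i)
        targ = []
        targ_set: set[str] = set()
        for cand in order:
            if len(targ) == n_targ:
                break
            linked = partners.get(cand, set()) & set(pool)
            if related_targets:
                # needs a partner that will end up in discovery
                if linked - targ_set - {cand}:
                    targ.append(cand)
                    targ_set.add(cand)
            else:
                if not linked:
                    targ.append(cand)
                    targ_set.add(cand)
        if len(targ) < n_targ:
            raise DesignError(
                f"cannot build {'TA' if related_targets else 'TB'} targets: "
                f"needed {n_targ}, found {len(targ)} eligible of {n} ids"
            )
        disc = [i for i in order if i not in targ_set]

    return StudyDesign(tuple(disc), tuple(targ), degree_label, scale_label, seed)
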