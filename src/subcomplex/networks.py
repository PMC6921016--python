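"""Characterizing predicted subunit networks.

For a complex of N subunits with M predicted physical edges the
*connection degree* is 2M / (N (N - 1)): the fraction of the complete
graph that is realized.  Complexes are triaged into

* ``fully``     -- connection degree >= ``full_threshold`` (default
  0.95: degree "equal to or extremely close to one"); these go to
  functional clustering, topology being uninformative;
* ``isolated``  -- no predicted edges at all;
* ``partially`` -- everything in between; these go to modularity
  clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

FULL_THRESHOLD = 0.95

FULLY = "fully"
PARTIALLY = "partially"
ISOLATED = "isolated"


@dataclass(frozen=True)
class ComplexProfile:
    complex_id: str
    n_subunits: int
    n_edges: int
    degree: float
    category: str


def connection_degree(n_subunits: int, n_edges: int) -> float:
    """2M / (N (N - 1)) for N subunits and M predicted edges."""
    if n_subunits < 2:
        raise ValueError("connection degree needs N >= 2")
    max_edges = n_subunits * (n_subunits - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValueError(
            f"edge count {n_edges} outside [0, {max_edges}] for N={n_subunits}"
        )
    return 2.0 * n_edges / (n_subunits * (n_subunits - 1))


def categorize(degree: float, n_edges: int, full_threshold: float = FULL_THRESHOLD) -> str:
    if n_edges == 0:
        return ISOLATED
    if degree >= full_threshold:
        return FULLY
    return PARTIALLY


def profile_complex(
    complex_id: str,
    members: Sequence[str],
    predicted: nx.Graph,
    full_threshold: float = FULL_THRESHOLD,
) -> ComplexProfile:
    """Profile one complex against its predicted subunit network."""
    n = len(members)
    members_set = set(members)
    m = sum(
        1
        for u, v in predicted.edges
        if u in members_set and v in members_set
    )
    degree = connection_degree(n, m)
    return ComplexProfile(complex_id, n, m, degree, categorize(degree, m, full_threshold))


def triage(
    complexes: Mapping[str, Sequence[str]],
    predicted: Mapping[str, nx.Graph],
    full_threshold: float = FULL_THRESHOLD,
) -> tuple[list[ComplexProfile], dict[str, float]]:
    """Profile every complex and report category fractions.

    Returns the profiles sorted by descending connection degree and the
    fractions of fully / partially / isolated complexes (summing to 1).
    """
    profiles = [
        profile_complex(cid, members, predicted[cid], full_threshold)
        for cid, members in complexes.items()
    ]
    profiles.sort(key=lambda p: (-p.degree, p.complex_id))
    total = len(profiles)
    fractions = {
        cat: (sum(1 for p in profiles if p.category == cat) / total if total else 0.0)
        for cat in (FULLY, PARTIALLY, ISOLATED)
    }
    return profiles, fractions


def write_profiles(profiles: Iterable[ComplexProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("# complex\tN\tM\tdegree\tcategory\n")
        for p in profiles:
            fh.write(
                f"{p.complex_id}\t{p.n_subunits}\t{p.n_edges}\t"
                f"{p.degree:.6f}\t{p.category}\n"
            )
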