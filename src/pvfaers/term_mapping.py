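"""Mapping reaction preferred terms to composite motor-complication endpoints.

Four levodopa motor complications are tracked.  Two exist as single MedDRA
preferred terms (on-off phenomenon, freezing phenomenon) and are matched
exactly; the other two (dyskinesia, wearing-off) are composites collected by
case-insensitive keyword search over the PT string — e.g. the dyskinesia
composite covers dyskinesia, dystonia, hyperkinesia, ballismus and alien
limb syndrome, and wearing-off covers incomplete or shortened therapeutic
response.  A case contributes at most once per endpoint no matter how many
member PTs it lists.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .io_faers import DATA_DIR, CaseReport, load_pt_soc

ENDPOINT_NAMES = ("dyskinesia", "wearing_off", "on_off_phenomenon", "freezing_phenomenon")


@dataclass(frozen=True)
class CompositeEndpoint:
    """A named endpoint with its match patterns.

    ``match_mode`` is ``exact_pt`` (case-insensitive string equality) or
    ``keyword`` (case-insensitive substring on the PT).
    """

    name: str
    patterns: tuple[str, ...]
    match_mode: str

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"endpoint {self.name!r} has no patterns")
        if self.match_mode not in ("exact_pt", "keyword"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")

    def matches(self, pt: str) -> bool:
        low = pt.lower()
        if self.match_mode == "exact_pt":
            return any(low == p for p in self.patterns)
        return any(p in low for p in self.patterns)


def load_endpoints(path: Path | str | None = None,
                   validate_against: Iterable[str] | None = None) -> list[CompositeEndpoint]:
    """Load the endpoint dictionary (columns: endpoint, pattern, match_mode).

    Endpoint member sets must be disjoint: validated by matching every
    pattern against the bundled PT vocabulary (or ``validate_against``) and
    requiring pairwise-disjoint hit sets.
    """
    path = Path(path) if path is not None else DATA_DIR / "endpoints.csv"
    grouped: dict[str, dict[str, list[str]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            mode = "keyword" if row["match_mode"].strip() == "keyword" else row["match_mode"].strip()
            grouped.setdefault(row["endpoint"].strip(), {}).setdefault(mode, []).append(
                row["pattern"].strip().lower())
    endpoints: list[CompositeEndpoint] = []
    for name, by_mode in grouped.items():
        if len(by_mode) != 1:
            raise ValueError(f"endpoint {name!r} mixes match modes")
        (mode, patterns), = by_mode.items()
        endpoints.append(CompositeEndpoint(name, tuple(patterns), mode))

    vocabulary = list(validate_against) if validate_against is not None else list(load_pt_soc())
    hit_sets = {e.name: {pt for pt in vocabulary if e.matches(pt)} for e in endpoints}
    names = [e.name for e in endpoints]
    for i, n1 in enumerate(names):
        for n2 in names[i + 1:]:
            shared = hit_sets[n1] & hit_sets[n2]
            if shared:
                raise ValueError(f"endpoints {n1!r} and {n2!r} overlap on {sorted(shared)}")
    return endpoints


def map_endpoints(case_or_pts: CaseReport | Iterable[str],
                  endpoints: Iterable[CompositeEndpoint]) -> dict[str, list[str]]:
    """Endpoint hits for one case: ``{endpoint_name: sorted matching PTs}``.

    For a :class:`CaseReport` the SOC-restricted analysis view is used when
    present.  The result is a pure function of the PT set (duplicates in the
    reaction list never change it) and every hit is traceable to the PTs that
    produced it.
    """
    if isinstance(case_or_pts, CaseReport):
        pts: Iterable[str] = case_or_pts.analysis_view
    else:
        pts = case_or_pts
    unique = sorted(set(pts))
    hits: dict[str, list[str]] = {}
    for endpoint in endpoints:
        matched = [pt for pt in unique if endpoint.matches(pt)]
        if matched:
            hits[endpoint.name] = matched
    return hits


def endpoint_set(case_or_pts: CaseReport | Iterable[str],
                 endpoints: Iterable[CompositeEndpoint]) -> set[str]:
    return set(map_endpoints(case_or_pts, endpoints))


def count_endpoint_hits(cases: Iterable[CaseReport],
                        endpoints: Iterable[CompositeEndpoint]) -> Mapping[str, int]:
    """Report-level endpoint counts (a case counts once per endpoint)."""
    endpoints = list(endpoints)
    counts = {e.name: 0 for e in endpoints}
    for case in cases:
        for name in map_endpoints(case, endpoints):
            counts[name] += 1
    return counts
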