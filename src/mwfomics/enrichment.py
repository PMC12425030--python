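"""Over-representation analysis of hit lists against GMT gene-set libraries.

The test is the one-sided (right-tail) Fisher exact / hypergeometric test
of the overlap between a query gene list and each gene set, against a
background universe of the genes assayed on the panel.  Reporting follows
the rule: per library, the top 5 most significant pathways or all with
p < 0.05, whichever is fewer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class GeneSetLibrary:
    """Named collection of gene sets (insertion-ordered)."""

    name: str
    sets: Dict[str, List[str]]
    descriptions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for set_name, members in self.sets.items():
            if len(members) == 0:
                raise InputError(f"gene set {set_name!r} in {self.name!r} is empty")


def read_gmt(path, name: Optional[str] = None) -> GeneSetLibrary:
    """Read a GMT file: one tab-separated line per set (name, description, members...)."""
    path = Path(path)
    sets: Dict[str, List[str]] = {}
    descriptions: Dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise InputError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
        set_name, description, members = parts[0], parts[1], [m for m in parts[2:] if m]
        if set_name in sets:
            raise InputError(f"{path}:{lineno}: duplicate set name {set_name!r}")
        if not members:
            raise InputError(f"{path}:{lineno}: gene set {set_name!r} has no members")
        sets[set_name] = members
        descriptions[set_name] = description
    return GeneSetLibrary(name=name or path.stem, sets=sets, descriptions=descriptions)


def write_gmt(library: GeneSetLibrary, path) -> None:
    """Write a library in GMT format; empty sets are rejected."""
    lines = []
    for set_name, members in library.sets.items():
        if len(members) == 0:
            raise InputError(f"gene set {set_name!r} is empty and cannot be written")
        description = library.descriptions.get(set_name, "")
        lines.append("\t".join([set_name, description, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


def _log_hypergeom_pmf(i: np.ndarray, K: int, n: int, N: int) -> np.ndarray:
    # log [ C(K,i) C(N-K, n-i) / C(N,n) ]
    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logC(K, i) + logC(N - K, n - i) - logC(N, n)


def fisher_right_tail(k: int, K: int, n: int, N: int) -> float:
    """Right-tail Fisher exact p: P(overlap >= k) under the hypergeometric null.

    k = observed overlap, K = set size within background, n = query size
    within background, N = background size.  Computed as a log-space sum
    of hypergeometric point masses for numerical stability.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ParameterError(f"{name} must be a non-negative integer, got {v!r}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N:
        raise ParameterError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ParameterError(f"k={k} exceeds min(K, n)={min(K, n)}")
    if k <= max(0, K + n - N):
        return 1.0  # the whole support is in the tail
    i = np.arange(k, min(K, n) + 1)
    p = float(np.exp(logsumexp(_log_hypergeom_pmf(i, K, n, N))))
    return min(p, 1.0)


def _odds_ratio(k: int, K: int, n: int, N: int) -> float:
    num = k * (N - K - n + k)
    den = (K - k) * (n - k)
    if den == 0:
        return float("inf") if k > 0 else float("nan")
    return num / den


def run_enrichment(
    query: Iterable[str],
    library: GeneSetLibrary,
    background: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher right-tail enrichment of a query list against one library.

    Query genes outside the background are dropped (count logged); set
    members are intersected with the background and sets that vanish
    (K = 0) are omitted.  Results are sorted by ascending p, ties broken
    by descending overlap k then set name, and carry a BH q-value across
    the library's sets.
    """
    bg = set(background)
    if not bg:
        raise InputError("background gene universe is empty")
    query = list(dict.fromkeys(query))  # de-dup, keep order
    q_in = [g for g in query if g in bg]
    dropped = len(query) - len(q_in)
    if dropped:
        logger.info("%s: dropped %d query genes outside the background", library.name, dropped)
    columns = ["library_name", "set_name", "k", "K", "n", "N", "p_value", "odds_ratio"]
    if not q_in:
        logger.warning("%s: query is empty after background intersection", library.name)
        out = pd.DataFrame(columns=columns + ["q_bh", "reported"])
        out.attrs["status"] = "empty_query"
        return out
    qset = set(q_in)
    N = len(bg)
    n = len(qset)
    rows = []
    for set_name, members in library.sets.items():
        mem = set(members) & bg
        K = len(mem)
        if K == 0:
            continue
        k = len(mem & qset)
        rows.append(
            {
                "library_name": library.name,
                "set_name": set_name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": fisher_right_tail(k, K, n, N),
                "odds_ratio": _odds_ratio(k, K, n, N),
            }
        )
    out = pd.DataFrame(rows, columns=columns)
    if len(out):
        from scipy import stats

        out["q_bh"] = stats.false_discovery_control(out["p_value"].to_numpy(), method="bh")
        out = out.sort_values(
            ["p_value", "k", "set_name"], ascending=[True, False, True], kind="mergesort"
        ).reset_index(drop=True)
    else:
        out["q_bh"] = []
    out["reported"] = False
    out.attrs["status"] = "ok"
    return out


def report_top(results: pd.DataFrame, alpha: float = 0.05, top_k: int = 5) -> pd.DataFrame:
    """Apply the per-library reporting rule.

    Per library, the first min(top_k, #{p < alpha}) rows (in the sorted
    order) get ``reported=True``.  Raw (unadjusted) p drives the rule.
    """
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    out = results.copy()
    out["reported"] = False
    if len(out) == 0:
        return out
    for _, idx in out.groupby("library_name", sort=False).groups.items():
        grp = out.loc[idx].sort_values(
            ["p_value", "k", "set_name"], ascending=[True, False, True], kind="mergesort"
        )
        n_report = min(top_k, int((grp["p_value"] < alpha).sum()))
        out.loc[grp.index[:n_report], "reported"] = True
    return out
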