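"""Population rankings from directional pairwise dominance.

A population *j* dominates *h* for a given aspect and domain when the
adjusted one-sided p-value for "j larger than h" is at or below alpha.
The rank of a population is one plus the number of populations that
dominate it, so ties share a rank and the result is always a weak order
("FM > M = F").  An intransitive significance pattern (A>B, B>C, C>A)
collapses to all-tied ranks and is flagged as cyclic rather than silently
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class RankingResult:
    aspect: str
    domain: str
    ranks: dict[str, int]
    dominance: set[tuple[str, str]]   # significant (winner, loser) pairs
    alpha: float
    cyclic: bool

    def __post_init__(self) -> None:
        if self.ranks and min(self.ranks.values()) != 1:
            raise ValueError("at least one population must hold rank 1")


def _has_cycle(edges: set[tuple[str, str]], nodes: list[str]) -> bool:
    graph = {n: [] for n in nodes}
    for a, b in edges:
        graph[a].append(b)
    state = {n: 0 for n in nodes}  # 0 unseen, 1 in stack, 2 done

    def dfs(n: str) -> bool:
        state[n] = 1
        for m in graph[n]:
            if state[m] == 1 or (state[m] == 0 and dfs(m)):
                return True
        state[n] = 2
        return False

    return any(state[n] == 0 and dfs(n) for n in nodes)


def rank_populations(matrix, alpha: float = 0.05, aspect: str = "",
                     domain: str = "", use_adjusted: bool = True) -> RankingResult:
    """Rank populations from a directional p-value matrix.

    ``matrix`` is either a :class:`~cytomorph.mastats.PValueMatrix` or a
    square DataFrame whose cell (j, h) is the one-sided p for "j > h".
    """
    if hasattr(matrix, "adjusted"):
        df = matrix.adjusted if use_adjusted else matrix.raw
        aspect = aspect or matrix.aspect
        domain = domain or matrix.domain
    else:
        df = matrix
    if not isinstance(df, pd.DataFrame) or df.shape[0] != df.shape[1]:
        raise ValueError("need a square directional p-value matrix")
    pops = list(df.index)
    dominance = {(j, h) for j in pops for h in pops
                 if j != h and df.loc[j, h] <= alpha}
    ranks = {p: 1 + sum(1 for (w, l) in dominance if l == p) for p in pops}
    # renormalize so the best rank is 1 even if every population is dominated
    shift = min(ranks.values()) - 1
    ranks = {p: r - shift for p, r in ranks.items()}
    return RankingResult(aspect, domain, ranks, dominance, alpha,
                         cyclic=_has_cycle(dominance, pops))


def format_ranking(result: RankingResult) -> str:
    """Render a weak order as text, e.g. ``"FM > M > F"`` or ``"F = M > FM"``.

    Populations are sorted by rank, alphabetical within ties; the cyclic
    flag is appended when the dominance relation is intransitive.
    """
    by_rank: dict[int, list[str]] = {}
    for pop, r in result.ranks.items():
        by_rank.setdefault(r, []).append(pop)
    parts = [" = ".join(sorted(by_rank[r])) for r in sorted(by_rank)]
    text = " > ".join(parts)
    if result.cyclic:
        text += " [cyclic dominance]"
    return text
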