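"""DOT export of the transition graph ("grapho").

Nodes are the four circumplex states; the 16 directed edges (self-loops
included) carry the transition probability at two decimals plus a percentage,
colored by transition geometry: vertical green, horizontal yellow (rendered
goldenrod for legibility), oblique orange, self gray.
"""

from __future__ import annotations

import networkx as nx

from .errors import AffectDynError
from .markov import INDEX_GROUPS, STATE_ORDER, TransitionMatrix
from .protocol import STATES

EDGE_COLORS = {
    "vertical": "green",
    "horizontal": "goldenrod",
    "oblique": "orange",
    "self": "gray",
}

_GROUP_OF = {pair: name for name, pairs in INDEX_GROUPS.items() for pair in pairs}


def transition_digraph(P: TransitionMatrix) -> nx.DiGraph:
    """The transition matrix as a networkx digraph with display attributes."""
    g = nx.DiGraph()
    for s in STATE_ORDER:
        g.add_node(s, label=f"{s}\\n{STATES[s].name}")
    for a in STATE_ORDER:
        for b in STATE_ORDER:
            p = P[a + b]
            group = _GROUP_OF[a + b]
            g.add_edge(
                a,
                b,
                weight=p,
                group=group,
                color=EDGE_COLORS[group],
                label=f"{p:.2f} ({p * 100:.0f}%)",
            )
    return g


def export_graph(P: TransitionMatrix, path) -> str:
    """Write the transition graph as a Graphviz DOT file; returns the text."""
    lines = ["digraph affect_transitions {", "  rankdir=LR;"]
    for s in STATE_ORDER:
        st = STATES[s]
        lines.append(
            f'  {s} [label="{s}\\n{st.name}", shape=circle];'
        )
    for a in STATE_ORDER:
        for b in STATE_ORDER:
            p = P[a + b]
            group = _GROUP_OF[a + b]
            lines.append(
                f'  {a} -> {b} [label="{p:.2f}", xlabel="{p * 100:.0f}%", '
                f'color={EDGE_COLORS[group]}, class="{group}"];'
            )
    lines.append("}")
    text = "\n".join(lines) + "\n"
    try:
        with open(path, "w") as fh:
            fh.write(text)
    except OSError as exc:
        raise AffectDynError(f"cannot write DOT file {path}: {exc}") from exc
    return text
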