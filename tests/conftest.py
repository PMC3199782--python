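import random

import pytest

from mitocircle.charmap import Node, Phylogeny


@pytest.fixture(scope="session")
def study_tree():
    from mitocircle.charmap import study_tree
    return study_tree()


@pytest.fixture(scope="session")
def study_matrix():
    from mitocircle.charmap import build_study_matrix
    return build_study_matrix()


def random_phylogeny(rng: random.Random, n_tips: int, polytomy_p: float = 0.25) -> Phylogeny:
    """Random rooted tree (possibly with polytomies) on tips t1..tn."""
    nodes = [Node(label=f"t{i + 1}") for i in range(n_tips)]
    while len(nodes) > 1:
        k = 3 if (len(nodes) >= 3 and rng.random() < polytomy_p) else 2
        picks = rng.sample(range(len(nodes)), k)
        children = [nodes[i] for i in picks]
        for i in sorted(picks, reverse=True):
            nodes.pop(i)
        nodes.append(Node(children=children))
    return Phylogeny(nodes[0])


def fitch_oracle(tree: Phylogeny, states: dict[str, str], root_state: str = "0") -> int:
    """Exhaustive minimum-change count over all internal labellings and all
    resolutions of unknown tips, with a virtual fixed-state ancestor above the
    root.  Independent of the production dynamic program."""
    internals = [n for n in tree.root.walk() if not n.is_tip]
    free_tips = [n for n in tree.root.walk() if n.is_tip and states.get(n.label, "?") == "?"]
    free = internals + free_tips
    best = None
    for mask in range(2 ** len(free)):
        assign = {}
        for i, n in enumerate(free):
            assign[id(n)] = str((mask >> i) & 1)
        def state_of(n):
            if n.is_tip and states.get(n.label, "?") != "?":
                return states[n.label]
            return assign[id(n)]
        changes = int(state_of(tree.root) != root_state)
        stack = [tree.root]
        while stack:
            n = stack.pop()
            for c in n.children:
                changes += int(state_of(c) != state_of(n))
                stack.append(c)
        if best is None or changes < best:
            best = changes
    return best
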