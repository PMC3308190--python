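import random

import pytest

from supertree.trees import Node, Tree


def random_binary_tree(labels, rng: random.Random, with_lengths=False) -> Tree:
    """Uniform-attachment random binary tree on the given labels."""
    labels = list(labels)
    assert len(labels) >= 3
    root = Node()
    for lb in labels[:3]:
        root.add(Node(lb))
    tree = Tree(root)
    for lb in labels[3:]:
        edges = [n for n in tree.preorder() if n.parent is not None]
        target = rng.choice(edges)
        parent = target.parent
        mid = Node()
        idx = parent.children.index(target)
        parent.children[idx] = mid
        mid.parent = parent
        target.parent = mid
        mid.children.append(target)
        mid.add(Node(lb))
    if with_lengths:
        for node in tree.preorder():
            if node.parent is not None:
                node.length = rng.uniform(0.02, 0.6)
    return tree


def random_topology(labels, rng: random.Random, polytomy_prob=0.3) -> Tree:
    """Random, possibly multifurcating tree (contract random edges)."""
    tree = random_binary_tree(labels, rng)
    for node in list(tree.preorder()):
        if (
            node.parent is not None
            and not node.is_leaf
            and rng.random() < polytomy_prob
        ):
            parent = node.parent
            node.detach()
            for child in list(node.children):
                child.detach()
                parent.add(child)
    return tree.normalize()


@pytest.fixture
def rng():
    return random.Random(20240917)
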