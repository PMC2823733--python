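import numpy as np
import pytest

from cladesig.simulate import ScenarioConfig, generate_scenario
from cladesig.tree import PhyloTree, TreeNode, parse_newick


@pytest.fixture(scope="session")
def default_scenario(tmp_path_factory):
    """Default synthetic scenario (seed 1) shared across the session."""
    outdir = tmp_path_factory.mktemp("scenario") / "s1"
    bundle = generate_scenario(ScenarioConfig(seed=1), str(outdir))
    return str(outdir), bundle


def random_binary_tree(n_leaves: int, rng: np.random.Generator,
                       min_len: float = 0.1, max_len: float = 1.0,
                       rooted: bool = True) -> PhyloTree:
    """Random binary topology with uniform branch lengths."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_leaves)]
    for node in nodes:
        node.length = float(rng.uniform(min_len, max_len))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(min_len, max_len)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for n in nodes:
        root.add_child(n)
    return PhyloTree(root, rooted=rooted)


def tree_path_distances(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """Additive leaf-to-leaf path-length matrix."""
    leaves = sorted(tree.leaf_names())
    idx = {t: i for i, t in enumerate(leaves)}
    D = np.zeros((len(leaves), len(leaves)))

    def walk(node, depth, acc):
        if node.is_leaf:
            acc[node.name] = depth
            return
        for c in node.children:
            walk(c, depth + c.length, acc)

    depths: dict[str, float] = {}
    walk(tree.root, 0.0, depths)

    # distance via LCA depths
    parent_of = {}
    depth_of = {tree.root: 0.0}
    for node in tree.root.traverse_preorder():
        for c in node.children:
            parent_of[c] = node
            depth_of[c] = depth_of[node] + c.length
    leaf_nodes = {n.name: n for n in tree.leaves()}

    def ancestors(node):
        out = []
        while node is not None:
            out.append(node)
            node = parent_of.get(node)
        return out

    for a in leaves:
        anc_a = ancestors(leaf_nodes[a])
        set_a = set(id(x) for x in anc_a)
        for b in leaves:
            if b <= a:
                continue
            node = leaf_nodes[b]
            while id(node) not in set_a:
                node = parent_of[node]
            lca = node
            d = depth_of[leaf_nodes[a]] + depth_of[leaf_nodes[b]] - 2 * depth_of[lca]
            D[idx[a], idx[b]] = D[idx[b], idx[a]] = d
    return leaves, D


@pytest.fixture
def quartet():
    return parse_newick("((A:1,B:2):1,(C:3,D:4):1)R;")
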