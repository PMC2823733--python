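"""Synthetic benchmark generator with machine-readable ground truth.

Generates, from a single seeded RNG: a clade-structured species tree
(outgroup pair; a deep-branching clade A; clade B containing the NOC
grouping; a free-standing "elongatus" lineage; clade C containing a
low-light-adapted subclade), universal housekeeping families, families
gained at chosen internal nodes (optionally lost in subtrees), ORFan
proteins, indels planted with frozen conserved flanks, and a 13-column
hit table whose E-values follow a phenomenological identity-driven model.
Every emitted file is reproducible byte-for-byte from the seed, and a
self-audit re-derives the truth records from the files.

Substitution model: along a branch of length ``t`` each site substitutes
independently with probability ``1 - exp(-t)``, replacement uniform over
the other 19 residues.  E-value model: ``E = 10**-(a + b*s + eps)`` with
``s`` the identity fraction and ``eps ~ Normal(0, sigma^2)``, clipped to
``[1e-180, 1]``.  Neither is a biological claim; they only need to induce
the orderings the downstream rules consume.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .msa import AA_LETTERS, GAP, MSA, write_fasta
from .tree import PhyloTree, TreeNode, parse_newick

_AA = np.frombuffer(AA_LETTERS.encode(), dtype=np.uint8)
_GAP_CODE = ord(GAP)


class ScenarioError(ValueError):
    pass


# -- default species tree template ---------------------------------------

def _group(prefix: str, k: int, name: str, stem: float,
           pendant: float = 0.03, inner: float = 0.02) -> str:
    """Named ladder subtree over leaves prefix1..prefixk; the named node is
    the true MRCA of the group (no unary wrappers)."""
    if k == 1:
        return f"{prefix}1:{stem}"
    node = f"{prefix}1:{pendant}"
    for i in range(2, k):
        node = f"({node},{prefix}{i}:{pendant}):{inner}"
    return f"({node},{prefix}{k}:{pendant}){name}:{stem}"


def default_template() -> str:
    nost = _group("Nost", 7, "Nostocales", 0.04)
    osc = _group("Osc", 4, "Oscillatoriales", 0.04)
    chro = _group("Chr", 4, "Chroococcales", 0.04)
    bother = _group("Bot", 5, "Bother", 0.02)
    sync = _group("SynC", 10, "SynCgrp", 0.02)
    hba = _group("HBA", 4, "HBA", 0.03)
    lba = _group("LBA", 6, "LowBA", 0.08)
    noc = f"({nost},({osc},{chro})OscChr:0.02)NOC:0.03"
    cladeb = f"({noc},{bother})CladeB:0.03"
    belong = f"({cladeb},Elo1:0.08)Belong:0.02"
    pro = f"({hba},{lba})Pro:0.04"
    cladec = f"({sync},{pro})CladeC:0.05"
    cladea = "((A1:0.04,A2:0.04):0.02,A3:0.05)CladeA:0.10"
    bce = f"({belong},{cladec})BCE:0.03"
    cyano = f"({cladea},{bce})Cyano:0.05"
    return f"((O1:0.10,O2:0.10)Outgroup:0.30,{cyano})Root;"


@dataclass(frozen=True)
class PlantedGroup:
    """Families gained at ``gain_node`` (optionally lost in subtrees),
    reported against ``target`` (a clade-expression string)."""

    prefix: str
    gain_node: str
    target: str
    count: int = 10
    loss_nodes: tuple[str, ...] = ()


@dataclass(frozen=True)
class IndelSpec:
    family: str                    # host family id (must be universal)
    node: str                      # carrier subtree (insert) / gapped subtree (deletion)
    length: tuple[int, int]        # residue length range drawn per carrier
    mode: str = "insert"           # insert | deletion
    flank: int = 5


def default_planted_groups() -> tuple[PlantedGroup, ...]:
    return (
        PlantedGroup("CY", "Cyano", "Cyano"),
        PlantedGroup("CA", "CladeA", "CladeA"),
        PlantedGroup("BC", "BCE", "ALL-CladeA"),
        PlantedGroup("CB", "CladeB", "CladeB"),
        PlantedGroup("BE", "Belong", "CladeB+Elongatus"),
        PlantedGroup("NO", "NOC", "NOC"),
        PlantedGroup("NS", "Nostocales", "Nostocales"),
        PlantedGroup("CH", "Chroococcales", "Chroococcales"),
        PlantedGroup("CC", "CladeC", "CladeC"),
        PlantedGroup("PR", "Pro", "Pro"),
        PlantedGroup("LB", "LowBA", "LowBA"),
        PlantedGroup("CL", "CladeC", "CladeC-LowBA", loss_nodes=("LowBA",)),
    )


def default_indel_specs() -> tuple[IndelSpec, ...]:
    # lengths 6, 2, 1 (deletion) and variable 4-5 in widely held families
    return (
        IndelSpec("U000", "CladeC", (6, 6), "insert"),
        IndelSpec("U001", "Pro", (2, 2), "insert"),
        IndelSpec("U002", "LowBA", (1, 1), "deletion"),
        IndelSpec("U003", "BCE", (4, 5), "insert"),
    )


@dataclass(frozen=True)
class ScenarioConfig:
    template: str = field(default_factory=default_template)
    n_universal_families: int = 40
    planted_groups: tuple[PlantedGroup, ...] = field(
        default_factory=default_planted_groups)
    n_orfans: int = 20
    indel_specs: tuple[IndelSpec, ...] = field(default_factory=default_indel_specs)
    root_len: int = 300
    decoy_rate: float = 0.0
    e_model: tuple[float, float, float] = (5.0, 100.0, 2.0)  # a, b, sigma
    seed: int = 1
    outgroup_taxa: tuple[str, ...] = ("O1", "O2")

    def with_seed(self, seed: int) -> "ScenarioConfig":
        from dataclasses import replace
        return replace(self, seed=seed)


# -- sequence evolution --------------------------------------------------

def evolve_family(tree: PhyloTree, root_len: int,
                  rng: np.random.Generator,
                  subtree: str | None = None) -> dict[str, np.ndarray]:
    """Evolve one family down the tree; returns leaf -> residue-index array.

    ``subtree`` restricts the family to the leaves under that named node
    (the gain node); sequences are arrays of indices into the 20 letters.
    The per-branch substitution probability is ``1 - exp(-t)``.
    """
    start = tree.find(subtree) if subtree is not None else tree.root
    root_seq = rng.integers(0, 20, size=root_len)
    out: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        if node.is_leaf:
            out[node.name] = seq  # type: ignore[index]
            return
        for child in node.children:
            p = 1.0 - math.exp(-child.length)
            mask = rng.random(len(seq)) < p
            child_seq = seq.copy()
            if mask.any():
                shift = rng.integers(1, 20, size=int(mask.sum()))
                child_seq[mask] = (child_seq[mask] + shift) % 20
            descend(child, child_seq)

    descend(start, root_seq)
    return out


@dataclass
class Family:
    fam_id: str
    gain_node: str
    loss_nodes: tuple[str, ...]
    target: str | None
    msa_ids: list[str]                 # taxon ids, fixed order
    msa: np.ndarray                    # (n_members, ncol) uint8 character codes
    indel: dict | None = None          # truth record when an indel is planted

    @property
    def members(self) -> list[str]:
        return self.msa_ids

    def ungapped(self, taxon: str) -> str:
        row = self.msa[self.msa_ids.index(taxon)]
        return bytes(row[row != _GAP_CODE]).decode("ascii")

    def to_msa(self) -> MSA:
        ids = [f"{self.fam_id}|{t}" for t in self.msa_ids]
        return MSA.from_array(ids, self.msa)


def _seqs_to_chars(seqs: dict[str, np.ndarray], order: list[str]) -> np.ndarray:
    return np.stack([_AA[seqs[t]] for t in order])


def plant_indel(family: Family, tree: PhyloTree, spec: IndelSpec,
                rng: np.random.Generator,
                root_seq_chars: np.ndarray) -> Family:
    """Insert a clade-restricted segment with frozen conserved flanks.

    ``insert`` mode: leaves under ``spec.node`` carry ``length`` residues,
    everyone else gets gap columns.  ``deletion`` mode: the reverse.  The
    ``flank`` columns on each side are overwritten with the root sequence
    in every member, guaranteeing flank conservation.
    """
    carriers_set = tree.leaves_under(spec.node)
    if spec.mode == "deletion":
        carriers_set = set(family.msa_ids) - carriers_set
    elif spec.mode != "insert":
        raise ScenarioError(f"unknown indel mode {spec.mode!r}")
    carriers = [t for t in family.msa_ids if t in carriers_set]
    if not carriers:
        raise ScenarioError(f"indel node {spec.node!r} has no carriers in family")

    F = spec.flank
    lmin, lmax = spec.length
    L = family.msa.shape[1]
    if L < 2 * F + 2:
        raise ScenarioError("sequence too short for locus + flanks")
    pos = int(rng.integers(F, L - F + 1))

    n = len(family.msa_ids)
    new = np.empty((n, L + lmax), dtype=np.uint8)
    new[:, :pos] = family.msa[:, :pos]
    new[:, pos + lmax:] = family.msa[:, pos:]
    new[:, pos:pos + lmax] = _GAP_CODE

    lengths = rng.integers(lmin, lmax + 1, size=len(carriers))
    if lmin < lmax:           # guarantee both extremes are realized
        lengths[0], lengths[1 % len(lengths)] = lmax, lmin
    for taxon, ln in zip(carriers, lengths):
        i = family.msa_ids.index(taxon)
        seg = _AA[rng.integers(0, 20, size=int(ln))]
        new[i, pos:pos + int(ln)] = seg

    # freeze flanks to the root state in every member
    new[:, pos - F:pos] = root_seq_chars[pos - F:pos]
    new[:, pos + lmax:pos + lmax + F] = root_seq_chars[pos:pos + F]

    truth = {
        "family": family.fam_id,
        "node": spec.node,
        "mode": spec.mode,
        "region": [pos, pos + lmax],
        "length_range": [int(lengths.min()), int(lengths.max())],
        "flank": F,
        "carriers": sorted(carriers),
        "polarity": "insert_in_clade" if spec.mode == "insert"
                    else "deletion_in_clade",
    }
    return Family(family.fam_id, family.gain_node, family.loss_nodes,
                  family.target, family.msa_ids, new, indel=truth)


# -- hit table -----------------------------------------------------------

def _family_hit_rows(fam: Family, e_model: tuple[float, float, float],
                     rng: np.random.Generator) -> list[str]:
    a, b, sigma = e_model
    n = len(fam.msa_ids)
    if n < 2:
        return []
    arr = fam.msa
    nongap = arr != _GAP_CODE
    comp = nongap[:, None, :] & nongap[None, :, :]
    eq = (arr[:, None, :] == arr[None, :, :]) & comp
    ncomp = comp.sum(axis=2)
    nmatch = eq.sum(axis=2)
    ident = np.where(ncomp > 0, nmatch / np.maximum(ncomp, 1), 0.0)
    eps = rng.normal(0.0, sigma, size=(n, n)) if sigma > 0 else np.zeros((n, n))
    expo = a + b * ident + eps
    evalues = np.clip(10.0 ** (-expo), 1e-180, 1.0)
    lens = [int(nongap[i].sum()) for i in range(n)]
    rows = []
    for i in range(n):
        qid = f"{fam.fam_id}|{fam.msa_ids[i]}"
        for j in range(n):
            if i == j:
                continue
            sid = f"{fam.fam_id}|{fam.msa_ids[j]}"
            s = float(ident[i, j])
            nc = int(ncomp[i, j])
            rows.append("\t".join((
                qid, sid, f"{100 * s:.1f}", str(nc),
                str(nc - int(nmatch[i, j])), "0",
                "1", str(lens[i]), "1", str(lens[j]),
                f"{float(evalues[i, j]):.6e}", f"{max(a + b * s, 0):.1f}",
                str(lens[j]))))
    return rows


def emit_hit_table(families: list[Family],
                   e_model: tuple[float, float, float],
                   rho: float, rng: np.random.Generator) -> list[str]:
    """13-column hit rows for all ordered within-family pairs, plus decoy
    rows joining non-homologous pairs with probability ``rho`` each."""
    rows: list[str] = []
    for fam in families:
        rows.extend(_family_hit_rows(fam, e_model, rng))
    if rho > 0:
        seqs = [(f"{fam.fam_id}|{t}", fam.fam_id, len(fam.ungapped(t)))
                for fam in families for t in fam.msa_ids]
        for qid, qfam, qlen in seqs:
            for sid, sfam, slen in seqs:
                if qfam == sfam:
                    continue
                if rng.random() < rho:
                    e = 10.0 ** rng.uniform(-4.0, 1.0)
                    rows.append("\t".join((
                        qid, sid, f"{rng.uniform(15, 25):.1f}",
                        str(min(qlen, slen) // 3), str(min(qlen, slen) // 4),
                        "1", "1", str(qlen // 3), "1", str(slen),
                        f"{e:.6e}", "25.0", str(slen))))
    return rows


# -- scenario ------------------------------------------------------------

@dataclass
class ScenarioBundle:
    config: ScenarioConfig
    tree: PhyloTree
    families: list[Family]
    hit_rows: list[str]
    truth: dict


def _named_internal_nodes(tree: PhyloTree) -> list[str]:
    return [n.name for n in tree.nodes() if not n.is_leaf and n.name]


def build_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Generate all families, indels and hit rows (in memory)."""
    tree = parse_newick(config.template)
    rng = np.random.default_rng(config.seed)
    leaves = sorted(tree.leaf_names())

    for grp in config.planted_groups:
        tree.find(grp.gain_node)
        gain_leaves = tree.leaves_under(grp.gain_node)
        for loss in grp.loss_nodes:
            loss_leaves = tree.leaves_under(loss)
            if not loss_leaves < gain_leaves:
                raise ScenarioError(
                    f"loss subtree {loss!r} is not strictly under gain node "
                    f"{grp.gain_node!r}")

    families: list[Family] = []

    def make_family(fam_id: str, gain_node: str | None,
                    loss_nodes: tuple[str, ...], target: str | None) -> Family:
        seqs = evolve_family(tree, config.root_len, rng, subtree=gain_node)
        lost: set[str] = set()
        for loss in loss_nodes:
            lost |= tree.leaves_under(loss)
        order = [t for t in sorted(seqs) if t not in lost]
        chars = _seqs_to_chars(seqs, order)
        start = tree.find(gain_node) if gain_node else tree.root
        return Family(fam_id, start.name or "Root", loss_nodes, target,
                      order, chars)

    # universal families (gained at the root, no losses)
    for i in range(config.n_universal_families):
        families.append(make_family(f"U{i:03d}", None, (), None))

    # planted clade families
    for grp in config.planted_groups:
        for i in range(grp.count):
            families.append(make_family(f"{grp.prefix}{i:03d}", grp.gain_node,
                                        grp.loss_nodes, grp.target))

    # ORFans: one random leaf each, unrelated sequence
    for i in range(config.n_orfans):
        taxon = leaves[int(rng.integers(0, len(leaves)))]
        seq = rng.integers(0, 20, size=config.root_len)
        families.append(Family(f"ORF{i:03d}", taxon, (), None, [taxon],
                               _seqs_to_chars({taxon: seq}, [taxon])))

    # plant indels (flanks frozen to a fresh reference state)
    by_id = {f.fam_id: f for f in families}
    for spec in config.indel_specs:
        if spec.family not in by_id:
            raise ScenarioError(f"indel host family {spec.family!r} not generated")
        host = by_id[spec.family]
        ref = _AA[rng.integers(0, 20, size=host.msa.shape[1])]
        planted = plant_indel(host, tree, spec, rng, ref)
        idx = families.index(host)
        families[idx] = planted
        by_id[spec.family] = planted

    hit_rows = emit_hit_table(families, config.e_model, config.decoy_rate, rng)

    truth = {
        "seed": config.seed,
        "n_taxa": len(leaves),
        "taxa": leaves,
        "outgroup": list(config.outgroup_taxa),
        "families": {
            f.fam_id: {
                "gain_node": f.gain_node,
                "loss_nodes": list(f.loss_nodes),
                "target": f.target,
                "members": f.msa_ids,
            } for f in families
        },
        "indels": {f.fam_id: f.indel for f in families if f.indel},
        "targets": sorted({g.target for g in config.planted_groups}),
        "groups": [
            {"prefix": g.prefix, "gain_node": g.gain_node, "target": g.target,
             "count": g.count, "loss_nodes": list(g.loss_nodes)}
            for g in config.planted_groups
        ],
    }
    return ScenarioBundle(config, tree, families, hit_rows, truth)


def write_scenario(bundle: ScenarioBundle, outdir: str) -> None:
    """Write every scenario artifact as plain text under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "proteomes"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "msas"), exist_ok=True)
    cfg = bundle.config
    tree = bundle.tree

    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(cfg.template.strip() + "\n")

    # clade definitions: every named internal node plus singleton Elongatus
    with open(os.path.join(outdir, "clades.tsv"), "w") as fh:
        for name in sorted(_named_internal_nodes(tree)):
            for t in sorted(tree.leaves_under(name)):
                fh.write(f"{name}\t{t}\n")
        if "Elo1" in tree.leaf_names():
            fh.write("Elongatus\tElo1\n")

    # taxonomy: every emitted sequence id
    outgroup = set(cfg.outgroup_taxa)
    with open(os.path.join(outdir, "taxonomy.tsv"), "w") as fh:
        rows = []
        for fam in bundle.families:
            for t in fam.msa_ids:
                tags = "outgroup" if t in outgroup else ""
                rows.append(f"{fam.fam_id}|{t}\t{t}\t{tags}")
        fh.write("\n".join(sorted(rows)) + "\n")

    # queries: one representative per family (smallest taxon id)
    with open(os.path.join(outdir, "queries.tsv"), "w") as fh:
        for fam in sorted(bundle.families, key=lambda f: f.fam_id):
            rep = min(fam.msa_ids)
            fh.write(f"{fam.fam_id}|{rep}\t{len(fam.ungapped(rep))}\t{rep}\n")

    with open(os.path.join(outdir, "targets.txt"), "w") as fh:
        seen: list[str] = []
        for grp in cfg.planted_groups:
            if grp.target not in seen:
                seen.append(grp.target)
        fh.write("\n".join(seen) + "\n")

    # CSI scan jobs: which alignments to inspect against which clade
    with open(os.path.join(outdir, "scan_jobs.tsv"), "w") as fh:
        for spec in cfg.indel_specs:
            fh.write(f"{spec.family}\t{spec.node}\n")

    # gene list for the supermatrix stage (families spanning every taxon)
    all_taxa = set(tree.leaf_names())
    with open(os.path.join(outdir, "genes.txt"), "w") as fh:
        for fam in sorted(bundle.families, key=lambda f: f.fam_id):
            if set(fam.msa_ids) == all_taxa:
                fh.write(fam.fam_id + "\n")

    with open(os.path.join(outdir, "hits.tsv"), "w") as fh:
        fh.write("\n".join(bundle.hit_rows) + ("\n" if bundle.hit_rows else ""))

    # proteomes
    by_taxon: dict[str, list[tuple[str, str]]] = {t: [] for t in
                                                  sorted(tree.leaf_names())}
    for fam in bundle.families:
        for t in fam.msa_ids:
            by_taxon[t].append((f"{fam.fam_id}|{t}", fam.ungapped(t)))
    for t, records in by_taxon.items():
        write_fasta(sorted(records), os.path.join(outdir, "proteomes", f"{t}.faa"))

    # true MSAs
    for fam in bundle.families:
        m = fam.to_msa()
        write_fasta(zip(m.ids, m.rows),
                    os.path.join(outdir, "msas", f"{fam.fam_id}.fasta"))

    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def generate_scenario(config: ScenarioConfig, outdir: str) -> ScenarioBundle:
    bundle = build_scenario(config)
    write_scenario(bundle, outdir)
    return bundle


def self_audit(outdir: str) -> None:
    """Re-derive truth records from the emitted files; raise on mismatch."""
    with open(os.path.join(outdir, "truth.json")) as fh:
        truth = json.load(fh)
    from .msa import read_alignment_file
    # tree must parse and cover every taxon in truth
    tree = parse_newick(open(os.path.join(outdir, "tree.nwk")).read())
    if sorted(tree.leaf_names()) != truth["taxa"]:
        raise ScenarioError("tree leaves differ from truth taxa")
    for fam_id, rec in truth["families"].items():
        msa = read_alignment_file(os.path.join(outdir, "msas", f"{fam_id}.fasta"))
        members = sorted(s.split("|", 1)[1] for s in msa.ids)
        if members != sorted(rec["members"]):
            raise ScenarioError(f"{fam_id}: MSA members differ from truth")
        for t in rec["members"]:
            path = os.path.join(outdir, "proteomes", f"{t}.faa")
            with open(path) as fh:
                if f">{fam_id}|{t}\n" not in fh.read():
                    raise ScenarioError(f"{fam_id}: member {t} missing from proteome")
    for fam_id, rec in truth["indels"].items():
        msa = read_alignment_file(os.path.join(outdir, "msas", f"{fam_id}.fasta"))
        lo, hi = rec["region"]
        carriers = set(rec["carriers"])
        for sid, row in zip(msa.ids, msa.rows):
            taxon = sid.split("|", 1)[1]
            seg = row[lo:hi]
            has_res = any(c != GAP for c in seg)
            if taxon in carriers and not has_res:
                raise ScenarioError(f"{fam_id}: carrier {taxon} lacks indel residues")
            if taxon not in carriers and has_res:
                raise ScenarioError(f"{fam_id}: non-carrier {taxon} holds residues")


# -- small fixed scenario for bootstrap behaviour ------------------------

DEEP_SPLIT_TEMPLATE = (
    "(((L1:0.05,L2:0.05):0.03,(L3:0.05,L4:0.05):0.03)Left:0.125,"
    "((R1:0.05,R2:0.05):0.03,(R3:0.05,R4:0.05):0.03)Right:0.125);"
)


def deep_split_alignment(seed: int = 7, ncol: int = 400) -> tuple[MSA, set[str]]:
    """8-taxon alignment with two groups separated by a long internal edge.

    Returns the alignment and the left-group leaf set (the planted split).
    """
    tree = parse_newick(DEEP_SPLIT_TEMPLATE)
    rng = np.random.default_rng(seed)
    seqs = evolve_family(tree, ncol, rng)
    order = sorted(seqs)
    msa = MSA.from_array(order, _seqs_to_chars(seqs, order))
    return msa, {"L1", "L2", "L3", "L4"}
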