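"""Simulator for two-paralog Twist-like protein families.

Generates a gene family descended from a single duplication with the
features every pipeline stage needs to be testable without downloads:

* a shared slow-evolving core (the bHLH-like block);
* a very slow N-terminal motif whose templates are the two mammalian
  motifs, with immutable class-specific columns including the N/T key
  residue (the duplication swaps the key threonine to asparagine on the
  group-A copy and replaces the motif with the group-A template, which
  carries one extra residue — the second aspartate column, gapped in
  every group-B row of the true alignment);
* fast-evolving disordered flanks;
* lineage-staged glycine-rich insertions on the group-A lineage only: a
  G-S region appearing on an early ("fish"-tier) branch and a G-A
  region on a later ("reptile/bird"-tier) branch, mirroring the order
  in which the two regions are inferred to have arisen.

Substitutions follow a per-site-class Poisson process with a
uniform-exchange model (a substitution picks a different residue
uniformly); insertions are atomic whole-region events.  Everything is
driven by a single integer seed and is byte-for-byte reproducible.

Because indels are restricted to the planted events, the simulator also
emits the exact true alignment (root coordinates plus the insertion
columns) alongside the unaligned records, the true gene tree, and the
coordinates of every planted feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skbio import TreeNode

from . import constants
from .seq_io import AMINO_ACIDS, GAP, Msa, SequenceRecord, read_newick

#: pectinate 12-tip species tree, fish → amphibian → reptile → bird → mammal
DEFAULT_SPECIES_TREE = (
    "(fish1:0.50,(fish2:0.45,(fish3:0.40,(amph1:0.35,(amph2:0.32,(rept1:0.28,"
    "(rept2:0.25,(bird1:0.22,(bird2:0.18,(mam1:0.12,(mam2:0.10,mam3:0.10):0.05)"
    ":0.06):0.05):0.05):0.05):0.05):0.05):0.05):0.05):0.05);"
)

DEFAULT_GS_REGION = "GGSGGGSSGG"
DEFAULT_GA_REGION = "GGAGGGAGGG"


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class InsertionEvent:
    """Atomic insertion of *region* at 1-based root position *position*
    on the group-A branch whose clade is exactly *clade_tips* (species
    names, without the paralog suffix)."""

    clade_tips: tuple
    region: str
    position: int


@dataclass(frozen=True)
class SimulationConfig:
    species_tree: str = DEFAULT_SPECIES_TREE
    #: species names below the duplication (None = duplication at the root,
    #: every species carries both paralogs)
    duplication_clade: Optional[tuple] = None
    #: expected substitutions per site per unit branch length
    rate_core: float = 0.02
    rate_motif: float = 0.005
    rate_disordered: float = 0.15
    #: inserted repeat regions are conserved; they evolve at the core rate
    rate_insertion: float = 0.02
    motif_template_a: str = constants.T1_MAMMAL_MOTIF
    motif_template_b: str = constants.T2_MAMMAL_MOTIF
    #: 1-based start of the motif on the root sequence
    motif_start: int = 5
    #: 1-based core (bHLH-like) interval on the root sequence
    core_range: tuple = (61, 120)
    insertion_events: tuple = (
        InsertionEvent(
            clade_tips=(
                "fish3", "amph1", "amph2", "rept1", "rept2",
                "bird1", "bird2", "mam1", "mam2", "mam3",
            ),
            region=DEFAULT_GS_REGION,
            position=30,
        ),
        InsertionEvent(
            clade_tips=("bird2", "mam1", "mam2", "mam3"),
            region=DEFAULT_GA_REGION,
            position=48,
        ),
    )
    root_length: int = 160
    #: stem branch length from the duplication node to each paralog copy
    dup_stem_length: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for r in (self.rate_core, self.rate_motif, self.rate_disordered, self.rate_insertion):
            if r < 0:
                raise ConfigError("substitution rates must be non-negative")
        if self.root_length < self.motif_start + len(self.motif_template_b):
            raise ConfigError("root too short for the motif")
        lo, hi = self.core_range
        if not (1 <= lo <= hi <= self.root_length):
            raise ConfigError("core range outside the root sequence")


@dataclass(frozen=True)
class SimulatedFamily:
    records: tuple  # SequenceRecords with true paralog_label
    true_tree: TreeNode  # gene tree (species tree + duplication)
    true_msa: Msa  # exact alignment (root coords + insertion columns)
    #: 1-based inclusive motif span on each ungapped record
    motif_spans: dict
    #: per record: list of (start, end, region subtype) for planted regions
    insertion_spans: dict
    #: 1-based alignment columns that are class-specific by construction
    class_specific_columns: tuple
    #: the alignment column carrying the N/T key residue
    key_column: int

    def records_by_label(self, label: str) -> list:
        return [r for r in self.records if r.paralog_label == label]


# alignment of the two motif templates: group A has one extra residue
# (the second aspartate) after template-B position 9
_A_EXTRA_AFTER_B_POS = 9
# class-specific template columns (1-based within template B): V/A, G/S, T/N
_CLASS_SPECIFIC_B_POS = (8, 12, 13)
_KEY_B_POS = 13  # the N/T key residue


def _gene_tree(config: SimulationConfig) -> TreeNode:
    species = read_newick(config.species_tree)
    sp_tips = [t.name for t in species.tips()]
    dup_clade = (
        tuple(sp_tips) if config.duplication_clade is None else config.duplication_clade
    )
    def clade_node(tree, tips):
        """Smallest node whose tip set equals *tips* (by name), else None."""
        want = frozenset(tips)
        for node in tree.postorder(include_self=True):
            if frozenset(t.name for t in node.tips(include_self=True)) == want:
                return node
        return None

    copy_b = read_newick(config.species_tree)
    if sorted(dup_clade) == sorted(sp_tips):
        copy_a = read_newick(config.species_tree)
        for tip in copy_b.tips():
            tip.name = f"{tip.name}_B"
        for tip in copy_a.tips():
            tip.name = f"{tip.name}_A"
        root = TreeNode(name="duplication")
        copy_b.length = config.dup_stem_length
        copy_a.length = config.dup_stem_length
        root.extend([copy_b, copy_a])
        return root
    node = clade_node(copy_b, dup_clade)
    if node is None:
        raise ConfigError(
            f"duplication clade {sorted(dup_clade)} is not a clade of the species tree"
        )
    copy_a = node.copy()
    for tip in copy_b.tips():
        tip.name = f"{tip.name}_B"
    for tip in copy_a.tips():
        tip.name = f"{tip.name}_A"
    # duplication below the root: split the branch above the clade
    parent = clade_node(copy_b, [f"{t}_B" for t in dup_clade])
    old_len = parent.length or 0.0
    grand = parent.parent
    grand.remove(parent)
    dup = TreeNode(name="duplication")
    dup.length = old_len / 2
    parent.length = old_len / 2
    copy_a.length = config.dup_stem_length
    dup.extend([parent, copy_a])
    grand.append(dup)
    copy_b.clear_caches()
    return copy_b


def simulate_family(config: SimulationConfig) -> SimulatedFamily:
    """Simulate one family; identical configs give identical output."""
    rng = np.random.default_rng(config.seed)
    tmpl_a, tmpl_b = config.motif_template_a, config.motif_template_b
    if len(tmpl_a) != len(tmpl_b) + 1:
        raise ConfigError("group-A motif template must be one residue longer")
    m0 = config.motif_start  # 1-based motif start on the root
    lb = len(tmpl_b)

    # ---- alignment column layout -----------------------------------------
    # root positions 1..root_length, plus the group-A motif insert column,
    # plus one block per insertion event, in left-to-right sequence order.
    inserts = []  # (root position after which the block sits, n columns, tag)
    inserts.append((m0 - 1 + _A_EXTRA_AFTER_B_POS, 1, "motifA"))
    for k, ev in enumerate(config.insertion_events):
        if not (1 <= ev.position <= config.root_length):
            raise ConfigError(f"insertion position {ev.position} outside root")
        inserts.append((ev.position - 1, len(ev.region), f"event{k}"))
    inserts.sort(key=lambda t: t[0])
    col_of_root = {}  # root position -> 0-based alignment column
    block_cols = {}  # tag -> list of 0-based alignment columns
    col = 0
    pending = list(inserts)
    for pos in range(1, config.root_length + 1):
        # blocks anchored after root position pos-1 sit before residue pos
        while pending and pending[0][0] == pos - 1:
            _, width, tag = pending.pop(0)
            block_cols[tag] = list(range(col, col + width))
            col += width
        col_of_root[pos] = col
        col += 1
    while pending:  # blocks anchored after the final residue
        _, width, tag = pending.pop(0)
        block_cols[tag] = list(range(col, col + width))
        col += width
    n_cols = col

    # ---- per-column site classes and rates -------------------------------
    rates = np.full(n_cols, config.rate_disordered)
    lo, hi = config.core_range
    for p in range(lo, hi + 1):
        rates[col_of_root[p]] = config.rate_core
    motif_cols_b = [col_of_root[m0 + i] for i in range(lb)]
    for c in motif_cols_b:
        rates[c] = config.rate_motif
    rates[block_cols["motifA"][0]] = config.rate_motif
    for k, ev in enumerate(config.insertion_events):
        for c in block_cols[f"event{k}"]:
            rates[c] = config.rate_insertion
    immutable = np.zeros(n_cols, dtype=bool)
    for bpos in _CLASS_SPECIFIC_B_POS:
        immutable[col_of_root[m0 + bpos - 1]] = True

    class_specific_cols = tuple(
        sorted(col_of_root[m0 + bpos - 1] + 1 for bpos in _CLASS_SPECIFIC_B_POS)
    )
    key_column = col_of_root[m0 + _KEY_B_POS - 1] + 1

    # ---- root state -------------------------------------------------------
    state = [GAP] * n_cols
    aa = list(AMINO_ACIDS)
    for p in range(1, config.root_length + 1):
        state[col_of_root[p]] = aa[rng.integers(len(aa))]
    for i, ch in enumerate(tmpl_b):
        state[col_of_root[m0 + i]] = ch

    # ---- events -----------------------------------------------------------
    tree = _gene_tree(config)

    def node_key(node):
        return frozenset(t.name for t in node.tips(include_self=True))

    events = {}  # frozenset of tips -> list of event callables
    a_tips = frozenset(t.name for t in tree.tips() if t.name.endswith("_A"))

    def motif_swap(s):
        # replace the motif region with the group-A template: template-B
        # columns with the insert column spliced in after B position
        # _A_EXTRA_AFTER_B_POS
        ordered = (
            [col_of_root[m0 + i] for i in range(_A_EXTRA_AFTER_B_POS)]
            + block_cols["motifA"]
            + [col_of_root[m0 + i] for i in range(_A_EXTRA_AFTER_B_POS, lb)]
        )
        for c, ch in zip(ordered, tmpl_a):
            s[c] = ch

    events.setdefault(a_tips, []).append(motif_swap)
    for k, ev in enumerate(config.insertion_events):
        clade = frozenset(f"{t}_A" for t in ev.clade_tips)
        cols = block_cols[f"event{k}"]
        region = ev.region

        def insert(s, cols=cols, region=region):
            for c, ch in zip(cols, region):
                s[c] = ch

        events.setdefault(clade, []).append(insert)

    # sanity: every event clade must be an actual clade of the gene tree
    tree_clades = {node_key(n) for n in tree.traverse(include_self=True)}
    for clade in events:
        if clade not in tree_clades:
            raise ConfigError(
                f"insertion clade {sorted(clade)} is not a clade of the gene tree"
            )

    # ---- evolve down the tree (preorder, deterministic) -------------------
    def evolve(s, t):
        out = list(s)
        for c in range(n_cols):
            if out[c] == GAP or immutable[c]:
                continue
            n_sub = rng.poisson(rates[c] * t)
            for _ in range(n_sub):
                cur = out[c]
                choices = [r for r in aa if r != cur]
                out[c] = choices[rng.integers(len(choices))]
        return out

    leaf_states = {}

    def walk(node, s):
        if node.parent is not None:
            s = evolve(s, node.length or 0.0)
        for clade, fns in events.items():
            if node_key(node) == clade:
                for fn in fns:
                    fn(s)
        if node.is_tip():
            leaf_states[node.name] = s
        else:
            for child in node.children:
                walk(child, s)

    walk(tree, state)

    # ---- assemble outputs -------------------------------------------------
    names = [t.name for t in tree.tips()]
    rows = tuple((name, "".join(leaf_states[name])) for name in names)
    msa = Msa(rows)
    records = []
    motif_spans = {}
    insertion_spans = {}
    region_subtype = {0: "G-S", 1: "G-A"}
    for name, row in rows:
        label = "group-A" if name.endswith("_A") else "group-B"
        rec = SequenceRecord(id=name, residues=row.replace(GAP, ""), paralog_label=label)
        records.append(rec)

        def ungapped_pos(c0):  # 0-based alignment col -> 1-based seq position
            return sum(1 for x in row[: c0 + 1] if x != GAP)

        first_motif_col = col_of_root[m0]
        last_motif_col = col_of_root[m0 + lb - 1]
        motif_spans[name] = (ungapped_pos(first_motif_col), ungapped_pos(last_motif_col))
        spans = []
        for k, ev in enumerate(config.insertion_events):
            cols = block_cols[f"event{k}"]
            if row[cols[0]] != GAP:
                spans.append(
                    (
                        ungapped_pos(cols[0]),
                        ungapped_pos(cols[-1]),
                        region_subtype.get(k, "other"),
                    )
                )
        insertion_spans[name] = spans
    return SimulatedFamily(
        records=tuple(records),
        true_tree=tree,
        true_msa=msa,
        motif_spans=motif_spans,
        insertion_spans=insertion_spans,
        class_specific_columns=class_specific_cols,
        key_column=key_column,
    )


def evolve_sequence(
    parent: SequenceRecord,
    branch_length: float,
    rates,
    rng,
    immutable=(),
) -> SequenceRecord:
    """Evolve one record along a branch.

    *rates* is a scalar or per-site array of expected substitutions per
    site per unit branch length; per site the substitution count is
    Poisson(rate × branch_length) and each substitution picks a
    different residue uniformly.  1-based positions in *immutable* never
    change.
    """
    if branch_length < 0:
        raise ValueError("branch length must be non-negative")
    n = len(parent)
    rate_arr = np.broadcast_to(np.asarray(rates, dtype=float), (n,))
    if (rate_arr < 0).any():
        raise ValueError("rates must be non-negative")
    frozen = set(immutable)
    aa = list(AMINO_ACIDS)
    out = list(parent.residues)
    for i in range(n):
        if (i + 1) in frozen:
            continue
        n_sub = rng.poisson(rate_arr[i] * branch_length)
        for _ in range(n_sub):
            cur = out[i]
            choices = [r for r in aa if r != cur]
            out[i] = choices[rng.integers(len(choices))]
    return SequenceRecord(
        id=parent.id,
        residues="".join(out),
        description=parent.description,
        paralog_label=parent.paralog_label,
    )
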