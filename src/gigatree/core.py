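"""Agglomerative gene-tree inference under species-tree and gene-content rules.

The engine walks the list of untreated sequence pairs in ascending p-distance
order. Each pair proposes an operation between the two orthologous subtrees
(OS's) currently containing the sequences:

* species sets overlap  -> the OS's are related by a gene duplication; the OS
  with the more recent species-tree MRCA is assigned a founding copy event
  (FCE) placed immediately prior to its MRCA, the most deletion-parsimonious
  placement (ties assign mutual FCEs to both);
* species sets disjoint -> the OS's are merged into one OS whose internal
  topology is the species-tree restriction over the union. A merge that would
  deepen an already-dated FCE requires significant distance evidence, in which
  case the FCE is revised rootward.

Sequences failing the fragment coverage test are quarantined during the main
pass and allowed a single re-insertion attempt afterwards. Everything is
deterministic: ties in the pair ordering break lexicographically on ids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignment import (
    DistanceMatrix,
    GAP_CODE,
    SaturationError,
    TrimmedAlignment,
    jc_stddev,
)
from .config import GigaConfig
from .genetree import DUPLICATION, GeneNode, GeneTree, LEAF, SPECIATION, UNRESOLVED
from .species_tree import SpeciesNode, SpeciesTree

__all__ = [
    "GigaError",
    "GigaInternalError",
    "OrthologousSubtree",
    "FoundingCopyEvent",
    "RevisionEvidence",
    "AgglomerationState",
    "GigaResult",
    "run_giga",
    "revision_test",
    "fragment_test",
    "EVENT_COLUMNS",
]


class GigaError(ValueError):
    pass


class GigaInternalError(RuntimeError):
    """Inconsistent internal state; carries the event log for debugging."""

    def __init__(self, message: str, events: list["Event"]):
        super().__init__(message)
        self.events = events


@dataclass
class FoundingCopyEvent:
    """The duplication that founded an OS.

    ``placement`` is the species-tree node immediately below the founding
    edge; the event happened on the edge entering that node (a virtual
    pre-root edge when the node is the species-tree root).
    """

    founded_os: int
    sibling_os: int
    placement: SpeciesNode


@dataclass
class OrthologousSubtree:
    """A group of sequences hypothesized to be related only by speciation."""

    id: int
    members: set[str]
    mrca: SpeciesNode
    fce: Optional[FoundingCopyEvent] = None

    def species(self, species_of: dict[str, str]) -> set[str]:
        return {species_of[m] for m in self.members}


EVENT_COLUMNS = (
    "step",
    "action",
    "seq1",
    "seq2",
    "os1",
    "os2",
    "distance",
    "detail",
)


@dataclass
class Event:
    step: int
    action: str
    seq1: str = ""
    seq2: str = ""
    os1: int = -1
    os2: int = -1
    distance: float = math.nan
    detail: str = ""

    def as_tsv(self) -> str:
        dist = "" if math.isnan(self.distance) else f"{self.distance:.6f}"
        return "\t".join(
            [
                str(self.step),
                self.action,
                self.seq1,
                self.seq2,
                str(self.os1) if self.os1 >= 0 else "",
                str(self.os2) if self.os2 >= 0 else "",
                dist,
                self.detail,
            ]
        )


@dataclass
class RevisionEvidence:
    """Distances and uncertainties backing an FCE revision decision."""

    dist1: float  # joining group <-> dated group
    std_dev1: float
    dist2: float  # joining group <-> sibling of the dated group
    std_dev2: float


def revision_test(
    ev: RevisionEvidence,
    alternative_implies_duplication: bool,
    cfg: GigaConfig = GigaConfig(),
) -> bool:
    """Is there adequate evidence to revise an already-dated duplication?

    The margin by which the joining group is closer to the dated group than
    to that group's sibling must exceed m*(sd1+sd2), with the stricter
    multiplier when the alternative hypothesis implies no duplication.
    """
    m = (
        cfg.paralog_sd_multiplier
        if alternative_implies_duplication
        else cfg.ortholog_sd_multiplier
    )
    margin = ev.dist1 - ev.dist2 if cfg.revision_literal_sign else ev.dist2 - ev.dist1
    return margin > m * (ev.std_dev1 + ev.std_dev2)


@dataclass
class AgglomerationState:
    """Mutable state of the iterative process."""

    sptree: SpeciesTree
    cfg: GigaConfig
    species_of: dict[str, str]
    oss: dict[int, OrthologousSubtree] = field(default_factory=dict)
    seq_to_os: dict[str, int] = field(default_factory=dict)
    alias: dict[int, int] = field(default_factory=dict)
    quarantined: list[str] = field(default_factory=list)
    discarded: list[str] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    step: int = 0

    def resolve(self, os_id: int) -> Optional[int]:
        """Follow merge aliases to the surviving OS id (None if gone)."""
        seen = set()
        while os_id in self.alias:
            if os_id in seen:  # defensive; aliases never cycle
                return None
            seen.add(os_id)
            os_id = self.alias[os_id]
        return os_id if os_id in self.oss else None

    def os_of(self, seq_id: str) -> OrthologousSubtree:
        return self.oss[self.seq_to_os[seq_id]]

    def log(self, action: str, **kw) -> None:
        self.events.append(Event(self.step, action, **kw))


@dataclass
class GigaResult:
    """Inference output: the labeled tree plus the audit trail."""

    tree: GeneTree
    events: list[Event]
    quarantined: list[str]  # sequences quarantined as fragments at any point
    discarded: list[str]  # fragments that could not be re-inserted
    state: AgglomerationState

    def event_log_tsv(self) -> str:
        lines = ["\t".join(EVENT_COLUMNS)]
        lines += [e.as_tsv() for e in self.events]
        return "\n".join(lines) + "\n"

    def duplication_placements(self) -> list[str]:
        """Species-tree node labels below each inferred duplication edge."""
        return sorted(
            n.species_label
            for n in self.tree.internal_nodes()
            if n.kind == DUPLICATION
        )


# ---------------------------------------------------------------------------
# Fragment detection (Rule 5)
# ---------------------------------------------------------------------------

def expected_sites(matrix: np.ndarray, member_rows: list[int]) -> np.ndarray:
    """Columns where more than half of the given sequences carry a residue."""
    present = matrix[member_rows] != GAP_CODE
    return present.sum(axis=0) > 0.5 * len(member_rows)


def fragment_test(
    candidate_row: int,
    merged_rows: list[int],
    matrix: np.ndarray,
    candidate_os_size: int,
    cfg: GigaConfig = GigaConfig(),
) -> bool:
    """True iff the candidate sequence looks like a fragment.

    A sequence already in an OS with at least ``cfg.fragment_exempt_os_size``
    other sequences is exempt: it survived earlier tests. Otherwise the
    candidate is a fragment iff it aligns no more than ``cfg.fragment_coverage``
    of the sites expected present in the merged group's ancestor (columns
    where more than half of the merged members *other than the candidate*
    carry a residue — the candidate does not get to vote on which sites it
    was expected to cover, otherwise a fragment driving a two-sequence merge
    would trivially certify itself).
    """
    if candidate_os_size - 1 >= cfg.fragment_exempt_os_size:
        return False
    others = [r for r in merged_rows if r != candidate_row]
    if not others:
        return False
    expected = expected_sites(matrix, others)
    n_expected = int(expected.sum())
    if n_expected == 0:
        return False
    aligned = int(((matrix[candidate_row] != GAP_CODE) & expected).sum())
    return aligned <= cfg.fragment_coverage * n_expected


# ---------------------------------------------------------------------------
# The engine
# ---------------------------------------------------------------------------

class _Engine:
    def __init__(
        self,
        trimmed: TrimmedAlignment,
        dm: DistanceMatrix,
        sptree: SpeciesTree,
        cfg: GigaConfig,
    ):
        self.trimmed = trimmed
        self.dm = dm
        self.sptree = sptree
        self.cfg = cfg
        self.ids = list(dm.ids)
        self.row = {sid: k for k, sid in enumerate(self.ids)}
        self.species_of = dict(zip(trimmed.ids, trimmed.species))
        missing = sorted(
            f"{sid} (species {sp})"
            for sid, sp in self.species_of.items()
            if sp not in sptree.leaf_index
        )
        if missing:
            raise GigaError(
                "sequences whose species is absent from the species tree: "
                + ", ".join(missing)
            )
        self.state = AgglomerationState(sptree, cfg, self.species_of)
        for k, sid in enumerate(self.ids):
            self.state.oss[k] = OrthologousSubtree(
                id=k, members={sid}, mrca=sptree.leaf(self.species_of[sid])
            )
            self.state.seq_to_os[sid] = k
        self._next_os_id = len(self.ids)
        self.frag_set: set[str] = set()

    # -- pair schedule ----------------------------------------------------

    def schedule(self) -> list[tuple[float, str, str]]:
        pairs = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                a, b = sorted((self.ids[i], self.ids[j]))
                pairs.append((self.dm.p[i, j], a, b))
        pairs.sort()
        return pairs

    # -- distance helpers --------------------------------------------------

    def group_distance(
        self, members_a: set[str], members_b: set[str]
    ) -> tuple[float, int]:
        """Minimum p-distance over inter-group pairs, with its site count."""
        best = (math.inf, 0, "", "")
        for a in sorted(members_a):
            ia = self.row[a]
            for b in sorted(members_b):
                ib = self.row[b]
                key = (self.dm.p[ia, ib], -self.dm.n[ia, ib], a, b)
                if key < (best[0], -best[1], best[2], best[3]):
                    best = (self.dm.p[ia, ib], int(self.dm.n[ia, ib]), a, b)
        return best[0], best[1]

    # -- operations --------------------------------------------------------

    def union_mrca(self, os1: OrthologousSubtree, os2: OrthologousSubtree) -> SpeciesNode:
        sp = os1.species(self.species_of) | os2.species(self.species_of)
        return self.sptree.mrca(sp)

    def attempt_join(
        self, os1: OrthologousSubtree, os2: OrthologousSubtree, a: str, b: str, p: float
    ) -> None:
        """Rule 2/3: relate two species-overlapping OS's by a duplication."""
        st = self.state
        # the genomic proof of duplication, recorded for event-log audits
        ov = ",".join(
            sorted(os1.species(self.species_of) & os2.species(self.species_of))
        )
        if os1.fce is not None and os2.fce is not None:
            st.log(
                "skip",
                seq1=a,
                seq2=b,
                os1=os1.id,
                os2=os2.id,
                distance=p,
                detail="both-fce-located",
            )
            return
        if os1.fce is None and os2.fce is None:
            # Rule 3: the OS with the more recent MRCA receives the FCE;
            # equal MRCAs assign mutual FCEs to both.
            if os1.mrca is os2.mrca:
                os1.fce = FoundingCopyEvent(os1.id, os2.id, os1.mrca)
                os2.fce = FoundingCopyEvent(os2.id, os1.id, os2.mrca)
                st.log(
                    "join",
                    seq1=a,
                    seq2=b,
                    os1=os1.id,
                    os2=os2.id,
                    distance=p,
                    detail=f"mutual-fce@{os1.mrca.label};overlap={ov}",
                )
            else:
                recent, older = (
                    (os1, os2)
                    if self.sptree.is_ancestor_or_self(os2.mrca, os1.mrca)
                    else (os2, os1)
                )
                recent.fce = FoundingCopyEvent(recent.id, older.id, recent.mrca)
                st.log(
                    "join",
                    seq1=a,
                    seq2=b,
                    os1=recent.id,
                    os2=older.id,
                    distance=p,
                    detail=f"fce@{recent.mrca.label};overlap={ov}",
                )
            return
        dated, undated = (os1, os2) if os1.fce is not None else (os2, os1)
        # 2.1.1.2: the undated OS's span must fit within the dated OS's span.
        if not self.sptree.is_ancestor_or_self(dated.mrca, undated.mrca):
            st.log(
                "refuse-join",
                seq1=a,
                seq2=b,
                os1=dated.id,
                os2=undated.id,
                distance=p,
                detail="span-exceeds-dated-os",
            )
        elif self._would_cycle(undated, dated):
            # an OS cannot, transitively, found itself
            st.log(
                "refuse-join",
                seq1=a,
                seq2=b,
                os1=dated.id,
                os2=undated.id,
                distance=p,
                detail="sibling-cycle",
            )
        else:
            undated.fce = FoundingCopyEvent(undated.id, dated.id, undated.mrca)
            st.log(
                "join",
                seq1=a,
                seq2=b,
                os1=undated.id,
                os2=dated.id,
                distance=p,
                detail=f"fce@{undated.mrca.label};overlap={ov}",
            )

    def _would_cycle(
        self, new_founded: OrthologousSubtree, sibling: OrthologousSubtree
    ) -> bool:
        """Would founding ``new_founded`` on ``sibling`` close a sibling
        cycle (beyond the allowed mutual pair)?"""
        seen: set[int] = set()
        cur = sibling
        while True:
            if cur.id == new_founded.id:
                return True
            if cur.fce is None or cur.id in seen:
                return False
            seen.add(cur.id)
            nxt = self.state.resolve(cur.fce.sibling_os)
            if nxt is None:
                return False
            cur = self.state.oss[nxt]

    def quarantine(self, seq_id: str, p: float, other: str) -> None:
        st = self.state
        os = st.os_of(seq_id)
        os.members.discard(seq_id)
        del st.seq_to_os[seq_id]
        if os.members:
            os.mrca = self.sptree.mrca(os.species(self.species_of))
        else:
            del st.oss[os.id]
        st.quarantined.append(seq_id)
        self.frag_set.add(seq_id)
        st.log(
            "quarantine",
            seq1=seq_id,
            seq2=other,
            os1=os.id,
            distance=p,
            detail="fragment",
        )

    def attempt_merge(
        self,
        os1: OrthologousSubtree,
        os2: OrthologousSubtree,
        a: str,
        b: str,
        p: float,
        check_fragments: bool = True,
    ) -> bool:
        """Rule 1 (+4, 5): merge two species-disjoint OS's into one."""
        st = self.state
        if check_fragments:
            merged_rows = sorted(
                self.row[m] for m in os1.members | os2.members
            )
            fragments = []
            for seq, other in ((a, b), (b, a)):
                os = st.os_of(seq)
                if fragment_test(
                    self.row[seq],
                    merged_rows,
                    self.trimmed.matrix,
                    len(os.members),
                    self.cfg,
                ):
                    fragments.append((seq, other))
            if fragments:
                for seq, other in fragments:
                    self.quarantine(seq, p, other)
                return False
        if os1.fce is not None and os2.fce is not None:
            st.log(
                "skip",
                seq1=a,
                seq2=b,
                os1=os1.id,
                os2=os2.id,
                distance=p,
                detail="both-fce-located",
            )
            return False
        if os1.fce is None and os2.fce is None:
            self._merge(os1, os2, a, b, p, detail="no-fce")
            return True
        dated, undated = (os1, os2) if os1.fce is not None else (os2, os1)
        union = self.union_mrca(os1, os2)
        if union is dated.mrca:
            # 2.1.2.3: no conflict with the established duplication date.
            self._merge(dated, undated, a, b, p, detail="mrca-unchanged")
            return True
        # 2.1.2.4: the merge would deepen the dated OS's MRCA; demand evidence.
        passed, detail = self._revision_evidence(dated, undated)
        if passed:
            old = dated.fce.placement.label
            dated.fce.placement = union
            self._merge(dated, undated, a, b, p, detail=f"revised:{old}->{union.label}")
            st.log(
                "revise-fce",
                seq1=a,
                seq2=b,
                os1=dated.id,
                os2=undated.id,
                distance=p,
                detail=f"{old}->{union.label};{detail}",
            )
            return True
        st.log(
            "refuse-merge",
            seq1=a,
            seq2=b,
            os1=dated.id,
            os2=undated.id,
            distance=p,
            detail=f"fce-conflict;{detail}",
        )
        return False

    def _revision_evidence(
        self, dated: OrthologousSubtree, undated: OrthologousSubtree
    ) -> tuple[bool, str]:
        st = self.state
        sibling_id = st.resolve(dated.fce.sibling_os)
        if sibling_id is None:
            return True, "sibling-gone"
        sibling = st.oss[sibling_id]
        if sibling is undated or sibling is dated:
            return False, "degenerate-sibling"
        dist1, n1 = self.group_distance(undated.members, dated.members)
        dist2, n2 = self.group_distance(undated.members, sibling.members)
        try:
            sd1 = jc_stddev(dist1, max(n1, 1), self.cfg.alphabet_states)
            sd2 = jc_stddev(dist2, max(n2, 1), self.cfg.alphabet_states)
        except SaturationError:
            return False, "saturated"
        implies_dup = bool(
            undated.species(self.species_of) & sibling.species(self.species_of)
        )
        ev = RevisionEvidence(dist1, sd1, dist2, sd2)
        ok = revision_test(ev, alternative_implies_duplication=implies_dup, cfg=self.cfg)
        return ok, (
            f"d1={dist1:.4f},d2={dist2:.4f},sd1={sd1:.4f},sd2={sd2:.4f},"
            f"alt-dup={implies_dup}"
        )

    def _merge(
        self,
        keep: OrthologousSubtree,
        absorb: OrthologousSubtree,
        a: str,
        b: str,
        p: float,
        detail: str,
    ) -> None:
        st = self.state
        # the OS carrying the FCE (if any) survives so sibling links stay valid
        if keep.fce is None and absorb.fce is not None:
            keep, absorb = absorb, keep
        keep.members |= absorb.members
        for m in absorb.members:
            st.seq_to_os[m] = keep.id
        st.alias[absorb.id] = keep.id
        del st.oss[absorb.id]
        keep.mrca = self.sptree.mrca(keep.species(self.species_of))
        st.log(
            "merge",
            seq1=a,
            seq2=b,
            os1=keep.id,
            os2=absorb.id,
            distance=p,
            detail=detail,
        )

    # -- phases ------------------------------------------------------------

    def main_pass(self) -> None:
        st = self.state
        for p, a, b in self.schedule():
            st.step += 1
            if a in self.frag_set or b in self.frag_set:
                continue
            osa, osb = st.os_of(a), st.os_of(b)
            if osa is osb:
                continue
            overlap = osa.species(self.species_of) & osb.species(self.species_of)
            if overlap:
                self.attempt_join(osa, osb, a, b, p)
            else:
                self.attempt_merge(osa, osb, a, b, p)

    def reinsert_fragments(self) -> None:
        st = self.state
        pending = list(st.quarantined)
        # ascending order of each fragment's best distance to any non-fragment
        ranked = []
        for frag in pending:
            fi = self.row[frag]
            best = (math.inf, "")
            for sid in sorted(st.seq_to_os):
                if sid in self.frag_set:
                    continue
                d = self.dm.p[fi, self.row[sid]]
                if (d, sid) < best:
                    best = (d, sid)
            ranked.append((best[0], frag, best[1]))
        ranked.sort()
        for p, frag, target_seq in ranked:
            st.step += 1
            if not target_seq:
                st.discarded.append(frag)
                st.log("discard", seq1=frag, detail="no-non-fragment-target")
                continue
            os_id = self._next_os_id
            self._next_os_id += 1
            frag_os = OrthologousSubtree(
                id=os_id,
                members={frag},
                mrca=self.sptree.leaf(self.species_of[frag]),
            )
            st.oss[os_id] = frag_os
            st.seq_to_os[frag] = os_id
            target = st.os_of(target_seq)
            if self.species_of[frag] in target.species(self.species_of):
                self.attempt_join(target, frag_os, target_seq, frag, p)
                placed = frag_os.fce is not None
            else:
                placed = self.attempt_merge(
                    target, frag_os, target_seq, frag, p, check_fragments=False
                )
            if placed:
                st.log("reinsert", seq1=frag, seq2=target_seq, distance=p)
            else:
                if st.resolve(os_id) == os_id and os_id in st.oss:
                    del st.oss[os_id]
                    del st.seq_to_os[frag]
                st.discarded.append(frag)
                st.log("discard", seq1=frag, seq2=target_seq, distance=p)

    # -- assembly ------------------------------------------------------------

    def os_subtree(self, os: OrthologousSubtree) -> GeneNode:
        """Species-tree restriction over the OS members (Rule 1 topology)."""
        by_species: dict[str, str] = {}
        for m in sorted(os.members):
            sp = self.species_of[m]
            if sp in by_species:
                raise GigaInternalError(
                    f"OS {os.id} holds two genes from {sp}", self.state.events
                )
            by_species[sp] = m

        def build(node: SpeciesNode) -> Optional[GeneNode]:
            if node.is_leaf:
                seq = by_species.get(node.label)
                if seq is None:
                    return None
                return GeneNode(LEAF, seq, node.label)
            kids = [k for k in (build(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return GeneNode(SPECIATION, species_label=node.label, children=kids)

        sub = build(os.mrca)
        if sub is None:
            raise GigaInternalError(
                f"OS {os.id} produced an empty subtree", self.state.events
            )
        return sub

    def assemble(self) -> GeneTree:
        st = self.state
        live = [st.oss[i] for i in sorted(st.oss)]
        subtree: dict[int, GeneNode] = {os.id: self.os_subtree(os) for os in live}

        def sibling_of(os: OrthologousSubtree) -> Optional[int]:
            if os.fce is None:
                return None
            return st.resolve(os.fce.sibling_os)

        # cycle check on the sibling digraph (mutual pairs allowed)
        for os in live:
            seen = {os.id}
            cur = os
            while cur.fce is not None:
                nxt = sibling_of(cur)
                if nxt is None:
                    break
                target = st.oss[nxt]
                if target.fce is not None and st.resolve(target.fce.sibling_os) == cur.id:
                    break  # mutual pair terminates the chain
                if nxt in seen:
                    raise GigaInternalError(
                        f"cycle in FCE sibling graph at OS {nxt}", st.events
                    )
                seen.add(nxt)
                cur = target

        mutual: set[frozenset[int]] = set()
        grafts: list[tuple[int, int, SpeciesNode]] = []  # (founded, sibling, placement)
        roots: list[int] = []
        for os in live:
            sib = sibling_of(os)
            if os.fce is None or sib is None:
                roots.append(os.id)
                continue
            partner = st.oss[sib]
            if partner.fce is not None and st.resolve(partner.fce.sibling_os) == os.id:
                mutual.add(frozenset((os.id, sib)))
            else:
                grafts.append((os.id, sib, os.fce.placement))

        # Mutual pairs (equal-MRCA joins) become a single duplication node
        # sitting above both subtrees; grafts into either member still find
        # their own subtree unchanged below it.
        for pair in sorted(mutual, key=lambda s: sorted(s)):
            id1, id2 = sorted(pair)
            os1, os2 = st.oss[id1], st.oss[id2]
            place = os1.fce.placement
            if self.sptree.is_ancestor_or_self(os2.fce.placement, place):
                place = os2.fce.placement  # rootward-most of the two
            GeneNode(
                DUPLICATION,
                species_label=place.label,
                children=[subtree[id1], subtree[id2]],
            )
            roots.append(id1)

        # Graft founded OS's onto their siblings. Rootward (older) placements
        # go first so that nested duplications on one lineage stack with the
        # older event above the more recent one.
        grafts.sort(key=lambda g: (g[2].depth, g[0]))
        for founded, sib, place in grafts:
            target_sub = subtree[sib]
            clade = self.sptree.clade_species(place)
            members_in = [
                leaf
                for leaf in target_sub.leaves()
                if self.species_of[leaf.label] in clade
            ]
            if members_in:
                labels = {leaf.label for leaf in members_in}
                graft_point = _mrca_node(target_sub, labels)
            else:
                graft_point = _component_top(target_sub)
            # attach the founded OS's whole component (earlier grafts may
            # already have stacked duplication nodes above its subtree)
            founded_top = _component_top(subtree[founded])
            parent = graft_point.parent
            if (
                parent is not None
                and parent.kind == DUPLICATION
                and parent.species_label == place.label
            ):
                parent.add_child(founded_top)
            else:
                dup = GeneNode(DUPLICATION, species_label=place.label)
                if parent is not None:
                    parent.children[parent.children.index(graft_point)] = dup
                    dup.parent = parent
                graft_point.parent = None
                dup.add_child(graft_point)
                dup.add_child(founded_top)

        component_roots = []
        seen_tops: set[int] = set()
        for os_id in roots:
            top = _component_top(subtree[os_id])
            if id(top) not in seen_tops:
                seen_tops.add(id(top))
                component_roots.append(top)
        component_roots.sort(key=lambda nd: min(nd.leaf_labels()))
        if len(component_roots) == 1:
            root = component_roots[0]
        else:
            root = GeneNode(UNRESOLVED, children=component_roots)
        return GeneTree(root)


def _component_top(node: GeneNode) -> GeneNode:
    while node.parent is not None:
        node = node.parent
    return node


def _mrca_node(root_node: GeneNode, labels: set[str]) -> GeneNode:
    top = _component_top(root_node)
    node = top
    while True:
        containing = [c for c in node.children if labels & c.leaf_labels()]
        if len(containing) == 1 and labels <= containing[0].leaf_labels():
            node = containing[0]
        else:
            return node


def run_giga(
    trimmed: TrimmedAlignment,
    dm: DistanceMatrix,
    sptree: SpeciesTree,
    cfg: GigaConfig = GigaConfig(),
) -> GigaResult:
    """Infer a labeled gene tree from a trimmed alignment and its distances.

    Deterministic: identical inputs yield identical trees and event logs.
    """
    engine = _Engine(trimmed, dm, sptree, cfg)
    engine.main_pass()
    engine.reinsert_fragments()
    tree = engine.assemble()
    st = engine.state
    return GigaResult(
        tree=tree,
        events=st.events,
        quarantined=list(st.quarantined),
        discarded=list(st.discarded),
        state=st,
    )
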