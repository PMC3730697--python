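"""A minimal rule-based stochastic simulation engine over site graphs.

Agents carry named sites; a site can hold an internal state (one of a
declared finite set), a bond to exactly one other site, or both, and a
signature may additionally declare integer counter sites.  Rules rewrite
partial patterns -- in the style of Kappa/BioNetGen -- and are simulated
with the exact Gillespie direct method, the propensity of a rule being
its stochastic rate constant times the number of embeddings (injective,
constraint-satisfying maps) of its left-hand pattern into the mixture.

Pattern site tests follow Kappa conventions: a mentioned site with no
bond mark must be unbound, ``!_`` means bound to anything, ``!n`` is a
shared bond label, and ``?`` leaves the bond untested.  Embedding counts
do not divide by pattern automorphisms: distinct orderings of identical
pattern agents count separately.

Randomness: one :class:`numpy.random.Generator` (PCG64) per trajectory,
consuming exactly three uniforms per event -- waiting time, rule choice,
embedding choice -- so trajectories are reproducible bit-for-bit given a
seed, independently of any internal caching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DefinitionError",
    "ApplicationError",
    "AgentSignature",
    "Agent",
    "Mixture",
    "SitePattern",
    "PatternAgent",
    "Pattern",
    "A",
    "Rule",
    "Model",
    "Trajectory",
    "count_embeddings",
    "apply_rule",
    "simulate",
    "run_ensemble",
    "enumerate_ctmc",
    "trajectory_to_tsv",
    "events_to_tsv",
]


class DefinitionError(ValueError):
    """A signature, pattern or rule is malformed."""


class ApplicationError(RuntimeError):
    """A rule was applied with an invalid or stale embedding."""


# Bond-test sentinels for SitePattern.bond (an int means a bond label).
ANY = "?"        # bond not tested
FREE = "."       # site must be unbound
BOUND = "_"      # site must be bound to something


class AgentSignature:
    """Agent type: named sites with allowed internal states, plus counters.

    A site with an empty state tuple is a pure binding site.
    """

    __slots__ = ("name", "sites", "counters")

    def __init__(self, name, sites=None, counters=()):
        self.name = name
        self.sites = {}
        for s, states in (sites or {}).items():
            if s in self.sites:
                raise DefinitionError(f"duplicate site {s!r} in {name}")
            self.sites[s] = tuple(states)
        self.counters = tuple(counters)
        if len(set(self.counters)) != len(self.counters):
            raise DefinitionError(f"duplicate counter in {name}")
        for c in self.counters:
            if c in self.sites:
                raise DefinitionError(f"{name}.{c} is both site and counter")

    def default_states(self):
        return {s: st[0] for s, st in self.sites.items() if st}

    def __repr__(self):
        return f"AgentSignature({self.name!r})"


class Agent:
    """One agent instance in a mixture."""

    __slots__ = ("id", "sig", "states", "bonds", "counters")

    def __init__(self, aid, sig, states, counters):
        self.id = aid
        self.sig = sig
        self.states = states          # site -> state value
        self.bonds = {}               # site -> (partner aid, partner site)
        self.counters = counters      # counter -> int

    def render(self):
        """Kappa-like text, one agent: ``RNAPII(a!1,e,ser5a~p)``."""
        parts = []
        for s in self.sig.sites:
            txt = s
            if s in self.states:
                txt += f"~{self.states[s]}"
            b = self.bonds.get(s)
            if b is not None:
                txt += f"!{b[0]}.{b[1]}"
            parts.append(txt)
        for c in self.sig.counters:
            parts.append(f"{c}{{{self.counters[c]}}}")
        return f"{self.sig.name}({','.join(parts)})"


class Mixture:
    """The full simulation state: a multiset of agents with bonds.

    Agent ids are unique and monotonically assigned; per-signature
    indices preserve ascending-id iteration order so that embedding
    enumeration is deterministic.
    """

    def __init__(self, signatures):
        self.signatures = {s.name: s for s in signatures}
        if len(self.signatures) != len(signatures):
            raise DefinitionError("signature names must be unique")
        self.agents = {}
        self.by_sig = {name: {} for name in self.signatures}
        self.time = 0.0
        self.event_count = 0
        self._next_id = 0

    # -- construction -------------------------------------------------
    def add_agent(self, sig_name, states=None, counters=None):
        sig = self.signatures.get(sig_name)
        if sig is None:
            raise DefinitionError(f"unknown signature {sig_name!r}")
        st = sig.default_states()
        for k, v in (states or {}).items():
            if k not in sig.sites:
                raise DefinitionError(f"unknown site {sig_name}.{k}")
            if v not in sig.sites[k]:
                raise DefinitionError(f"state {v!r} not allowed for {sig_name}.{k}")
            st[k] = v
        cn = {c: 0 for c in sig.counters}
        cn.update(counters or {})
        ag = Agent(self._next_id, sig, st, cn)
        self.agents[ag.id] = ag
        self.by_sig[sig_name][ag.id] = None
        self._next_id += 1
        return ag

    def remove_agent(self, aid):
        ag = self.agents.pop(aid)
        for s, b in list(ag.bonds.items()):
            if b is not None:
                pa, ps = b
                self.agents[pa].bonds[ps] = None
        del self.by_sig[ag.sig.name][aid]
        return ag

    def bind(self, a1, s1, a2, s2):
        g1, g2 = self.agents[a1], self.agents[a2]
        if g1.bonds.get(s1) is not None or g2.bonds.get(s2) is not None:
            raise ApplicationError(
                f"bind to occupied site: {g1.render()} / {g2.render()}")
        g1.bonds[s1] = (a2, s2)
        g2.bonds[s2] = (a1, s1)

    def unbind(self, a1, s1):
        g1 = self.agents[a1]
        b = g1.bonds.get(s1)
        if b is None:
            raise ApplicationError(f"unbind of free site {g1.sig.name}.{s1}")
        self.agents[b[0]].bonds[b[1]] = None
        g1.bonds[s1] = None
        return b

    def copy(self):
        m = Mixture(list(self.signatures.values()))
        m.time = self.time
        m.event_count = self.event_count
        m._next_id = self._next_id
        for aid, ag in self.agents.items():
            c = Agent(aid, ag.sig, dict(ag.states), dict(ag.counters))
            c.bonds = dict(ag.bonds)
            m.agents[aid] = c
            m.by_sig[ag.sig.name][aid] = None
        return m

    # -- validation & rendering ---------------------------------------
    def validate(self):
        """Check bond symmetry, dangling references and state legality."""
        for aid, ag in self.agents.items():
            for s, v in ag.states.items():
                if v not in ag.sig.sites[s]:
                    raise DefinitionError(f"illegal state {v!r} at {aid}.{s}")
            for s, b in ag.bonds.items():
                if b is None:
                    continue
                pa, ps = b
                other = self.agents.get(pa)
                if other is None or other.bonds.get(ps) != (aid, s):
                    raise DefinitionError(f"asymmetric bond at agent {aid}.{s}")
        return True

    def render(self):
        """Debug snapshot: one agent per line, Kappa-like, id-sorted."""
        return "\n".join(self.agents[i].render() for i in sorted(self.agents))

    def canonical(self):
        """Hashable full-state key (labelled by agent id)."""
        out = []
        for aid in sorted(self.agents):
            ag = self.agents[aid]
            out.append((aid, ag.sig.name,
                        tuple(sorted(ag.states.items())),
                        tuple(sorted((s, b) for s, b in ag.bonds.items()
                                     if b is not None)),
                        tuple(sorted(ag.counters.items()))))
        return tuple(out)

    def count(self, sig_name):
        return len(self.by_sig.get(sig_name, ()))


# ----------------------------------------------------------------------
# Patterns
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SitePattern:
    """Tests on one site: internal state, bond status, counter value."""
    state: str | None = None          # None = not tested
    bond: object = ANY                # ANY | FREE | BOUND | int label
    counter: tuple | None = None      # (op, value), op in {">=", "=", "<="}


def _parse_site_spec(spec):
    """Parse one site spec string into (site_name, SitePattern).

    Grammar (Kappa-flavoured): ``a`` free, ``a!_`` bound-to-anything,
    ``a!1`` bond label, ``a?`` bond untested, ``a~p`` adds a state test
    (state defaults the bond test to "free" unless a bond mark follows),
    ``n>=1`` / ``n=0`` / ``n<=2`` counter tests.
    """
    for op in (">=", "<=", "="):
        if op in spec and "~" not in spec and "!" not in spec:
            name, val = spec.split(op, 1)
            return name, SitePattern(counter=(op, int(val)))
    bond = FREE
    state = None
    name = spec
    if "!" in name:
        name, b = name.split("!", 1)
        bond = BOUND if b == "_" else int(b)
    elif name.endswith("?"):
        name = name[:-1]
        bond = ANY
    if "~" in name:
        name, state = name.split("~", 1)
    return name, SitePattern(state=state, bond=bond)


class PatternAgent:
    """One agent of a pattern: signature name plus per-site tests."""

    __slots__ = ("sig_name", "sites")

    def __init__(self, sig_name, sites):
        self.sig_name = sig_name
        self.sites = sites            # site -> SitePattern

    def render(self):
        parts = []
        for s, sp in self.sites.items():
            if sp.counter is not None:
                parts.append(f"{s}{sp.counter[0]}{sp.counter[1]}")
                continue
            txt = s
            if sp.state is not None:
                txt += f"~{sp.state}"
            if sp.bond is BOUND:
                txt += "!_"
            elif sp.bond is ANY:
                txt += "?"
            elif sp.bond is not FREE:
                txt += f"!{sp.bond}"
            parts.append(txt)
        return f"{self.sig_name}({','.join(parts)})"


def A(sig_name, *site_specs):
    """Build a PatternAgent from site spec strings (see module docs)."""
    sites = {}
    for spec in site_specs:
        name, sp = _parse_site_spec(spec)
        if name in sites:
            raise DefinitionError(f"site {name!r} mentioned twice")
        sites[name] = sp
    return PatternAgent(sig_name, sites)


class Pattern:
    """An ordered list of PatternAgents with shared bond labels."""

    def __init__(self, agents):
        self.agents = list(agents)
        # label -> [(agent index, site)]
        self.labels = {}
        for i, pa in enumerate(self.agents):
            for s, sp in pa.sites.items():
                if isinstance(sp.bond, int):
                    self.labels.setdefault(sp.bond, []).append((i, s))
        for lab, eps in self.labels.items():
            if len(eps) != 2:
                raise DefinitionError(
                    f"bond label {lab} appears {len(eps)} times (need 2)")

    def validate(self, signatures):
        for pa in self.agents:
            sig = signatures.get(pa.sig_name)
            if sig is None:
                raise DefinitionError(f"unknown signature {pa.sig_name!r}")
            for s, sp in pa.sites.items():
                if sp.counter is not None:
                    if s not in sig.counters:
                        raise DefinitionError(
                            f"{pa.sig_name}.{s} is not a counter")
                elif s not in sig.sites:
                    raise DefinitionError(f"unknown site {pa.sig_name}.{s}")
                elif sp.state is not None and sp.state not in sig.sites[s]:
                    raise DefinitionError(
                        f"state {sp.state!r} not allowed for {pa.sig_name}.{s}")

    def render(self):
        return ", ".join(pa.render() for pa in self.agents)


def _counter_ok(op, have, want):
    if op == ">=":
        return have >= want
    if op == "<=":
        return have <= want
    return have == want


# compiled site-check opcodes
_CK_STATE, _CK_FREE, _CK_BOUND, _CK_LABEL, _CK_CTR = range(5)


def _compile_checks(pattern):
    """Per pattern agent, an ordered tuple of site checks (cheap state
    tests first, bond-label consistency last) for the matcher."""
    compiled = []
    for i, pa in enumerate(pattern.agents):
        checks = []
        for s, sp in pa.sites.items():
            if sp.counter is not None:
                checks.append((0, _CK_CTR, s, sp.counter))
                continue
            if sp.state is not None:
                checks.append((0, _CK_STATE, s, sp.state))
            b = sp.bond
            if b is FREE:
                checks.append((1, _CK_FREE, s, None))
            elif b is BOUND:
                checks.append((1, _CK_BOUND, s, None))
            elif isinstance(b, int):
                eps = pattern.labels[b]
                oi, osite = eps[0] if eps[1] == (i, s) else eps[1]
                checks.append((2, _CK_LABEL, s,
                               (oi, osite, pattern.agents[oi].sig_name)))
        checks.sort(key=lambda c: c[0])
        compiled.append(tuple((k, s, a) for _, k, s, a in checks))
    return compiled


def _make_plan(pattern):
    """Static matching order: follow bond labels from already-placed
    agents where possible; otherwise anchor at the most-constrained
    unplaced agent.  Deterministic for a given pattern."""
    n = len(pattern.agents)
    placed = []
    links = []          # per step: None or (placed_pidx, placed_site, my_site)
    remaining = list(range(n))
    score = [len(pattern.agents[i].sites) for i in range(n)]
    while remaining:
        link = None
        chosen = None
        for i in remaining:
            for s, sp in pattern.agents[i].sites.items():
                if isinstance(sp.bond, int):
                    eps = pattern.labels[sp.bond]
                    other = eps[0] if eps[1] == (i, s) else eps[1]
                    if other[0] in placed:
                        link = (other[0], other[1], s)
                        chosen = i
                        break
            if chosen is not None:
                break
        if chosen is None:
            chosen = max(remaining, key=lambda i: (score[i], -i))
        placed.append(chosen)
        links.append(link)
        remaining.remove(chosen)
    return placed, links, _compile_checks(pattern)


def _match(pattern, mixture, plan=None):
    """All embeddings of pattern into mixture, in canonical order.

    Returns a list of tuples of agent ids aligned with pattern.agents.
    """
    n = len(pattern.agents)
    if n == 0:
        return [()]
    if plan is None:
        plan = _make_plan(pattern)
    order, links, checks = plan
    agents = mixture.agents
    by_sig = mixture.by_sig
    assign = [None] * n
    used = set()
    out = []

    def bt(k):
        if k == n:
            out.append(tuple(assign))
            return
        pidx = order[k]
        pa = pattern.agents[pidx]
        link = links[k]
        if link is not None:
            opidx, osite, mysite = link
            b = agents[assign[opidx]].bonds.get(osite)
            cands = () if b is None or b[1] != mysite else (b[0],)
        else:
            cands = by_sig.get(pa.sig_name, ())
        my_checks = checks[pidx]
        for aid in cands:
            if aid in used:
                continue
            ag = agents[aid]
            if ag.sig.name != pa.sig_name:
                continue
            states = ag.states
            bonds = ag.bonds
            ok = True
            for kind, s, arg in my_checks:
                if kind == _CK_STATE:
                    if states.get(s) != arg:
                        ok = False
                        break
                elif kind == _CK_FREE:
                    if bonds.get(s) is not None:
                        ok = False
                        break
                elif kind == _CK_BOUND:
                    if bonds.get(s) is None:
                        ok = False
                        break
                elif kind == _CK_LABEL:
                    actual = bonds.get(s)
                    if actual is None or actual[1] != arg[1]:
                        ok = False
                        break
                    oi = arg[0]
                    if assign[oi] is not None:
                        if actual[0] != assign[oi]:
                            ok = False
                            break
                    elif agents[actual[0]].sig.name != arg[2]:
                        ok = False
                        break
                else:  # counter
                    if not _counter_ok(arg[0], ag.counters[s], arg[1]):
                        ok = False
                        break
            if not ok:
                continue
            assign[pidx] = aid
            used.add(aid)
            bt(k + 1)
            used.discard(aid)
            assign[pidx] = None

    bt(0)
    out.sort()
    return out


def count_embeddings(pattern, mixture):
    """Number of embeddings of ``pattern`` in ``mixture``, plus the list.

    Distinct orderings of identical pattern agents count separately (no
    automorphism division).
    """
    pattern.validate(mixture.signatures)
    emb = _match(pattern, mixture)
    return len(emb), emb


# ----------------------------------------------------------------------
# Rules
# ----------------------------------------------------------------------

def _parse_counter_action(spec):
    """rhs counter ops: ``rna+=30`` or ``rna:=0``."""
    if "+=" in spec:
        name, v = spec.split("+=", 1)
        return name, ("inc", int(v))
    if ":=" in spec:
        name, v = spec.split(":=", 1)
        return name, ("set", int(v))
    return None


class Rule:
    """A rewrite: left pattern, right pattern, stochastic rate constant.

    The right-hand side aligns positionally with the left: entry ``None``
    deletes the corresponding agent, extra entries create agents (their
    sites must be fully specified).  Actions are derived as exactly the
    lhs -> rhs difference.
    """

    def __init__(self, name, lhs, rhs, rate, rate_name=None):
        self.name = name
        self.lhs = lhs if isinstance(lhs, Pattern) else Pattern(lhs)
        self.rate = float(rate)
        self.rate_name = rate_name or repr(rate)
        if self.rate < 0:
            raise DefinitionError(f"negative rate in rule {name!r}")
        # split rhs agent specs from counter actions
        self._rhs_raw = list(rhs)
        self.rhs_agents = []
        self.counter_actions = []     # (lhs index, counter, op tuple)
        for i, ra in enumerate(self._rhs_raw):
            if ra is None or isinstance(ra, PatternAgent):
                self.rhs_agents.append(ra)
            else:
                raise DefinitionError("rhs entries must be PatternAgent or None")
        self.actions = []
        self._derive()
        self._plan = None

    # -- derivation ----------------------------------------------------
    def _derive(self):
        lhs_agents = self.lhs.agents
        n = len(lhs_agents)
        rhs = self.rhs_agents
        if len(rhs) < n:
            raise DefinitionError(f"rule {self.name!r}: rhs shorter than lhs")
        # rhs bond-label endpoint map: label -> [(agent index, site)]
        rhs_labels = {}
        for i, ra in enumerate(rhs):
            if ra is None:
                continue
            for s, sp in ra.sites.items():
                if isinstance(sp.bond, int):
                    rhs_labels.setdefault(sp.bond, []).append((i, s))
        for lab, eps in rhs_labels.items():
            if len(eps) != 2:
                raise DefinitionError(
                    f"rule {self.name!r}: rhs label {lab} not paired")
        lhs_labels = self.lhs.labels

        deletes, creates, sets, unbinds, binds, moves, cacts = \
            [], [], [], [], [], [], []

        for i in range(n):
            la, ra = lhs_agents[i], rhs[i]
            if ra is None:
                deletes.append(("delete", i))
                continue
            if ra.sig_name != la.sig_name:
                raise DefinitionError(
                    f"rule {self.name!r}: rhs agent {i} changes signature")
            for s, rsp in ra.sites.items():
                lsp = la.sites.get(s, SitePattern())
                if rsp.counter is not None:
                    raise DefinitionError(
                        f"rule {self.name!r}: counter test on rhs")
                if rsp.state is not None and rsp.state != lsp.state:
                    sets.append(("set", i, s, rsp.state))
        # created agents
        for j in range(n, len(rhs)):
            ra = rhs[j]
            if ra is None:
                raise DefinitionError(f"rule {self.name!r}: rhs None beyond lhs")
            states = {}
            counters = {}
            for s, sp in ra.sites.items():
                if sp.counter is not None:
                    if sp.counter[0] != "=":
                        raise DefinitionError(
                            f"rule {self.name!r}: created counter needs '='")
                    counters[s] = sp.counter[1]
                elif sp.state is not None:
                    states[s] = sp.state
            creates.append(("create", j, ra.sig_name, states, counters))

        # bond differences
        def lhs_bond(i, s):
            if i >= n or rhs[i] is None:
                return None
            return lhs_agents[i].sites.get(s, SitePattern()).bond

        handled = set()
        for lab, eps in rhs_labels.items():
            (i1, s1), (i2, s2) = eps
            lb1, lb2 = lhs_bond(i1, s1), lhs_bond(i2, s2)
            if isinstance(lb1, int) and lb1 == lb2 and \
                    set(lhs_labels.get(lb1, ())) == {(i1, s1), (i2, s2)}:
                continue  # bond untouched
            binds.append(("bind", i1, s1, i2, s2))
            for (i, s), lb in (((i1, s1), lb1), ((i2, s2), lb2)):
                if isinstance(lb, int) or lb is BOUND:
                    # endpoint was bound: the old bond is replaced
                    moves.append((i, s))
                    handled.add((i, s))
        for lab, eps in lhs_labels.items():
            for (i, s) in eps:
                if i >= n or rhs[i] is None or (i, s) in handled:
                    continue
                rb = rhs[i].sites.get(s, SitePattern(bond=ANY)).bond
                if rb is FREE:
                    other = eps[0] if eps[1] == (i, s) else eps[1]
                    unbinds.append(("unbind", i, s, other in moves))
                    handled.add((i, s))
                    handled.add(other)
                elif rb is ANY or isinstance(rb, int):
                    pass
                else:
                    raise DefinitionError(
                        f"rule {self.name!r}: bad rhs bond at agent {i}.{s}")
        # explicit unbinds of BOUND-tested sites
        for i in range(n):
            if rhs[i] is None:
                continue
            for s, lsp in lhs_agents[i].sites.items():
                if lsp.bond is BOUND and (i, s) not in handled:
                    rb = rhs[i].sites.get(s, SitePattern(bond=ANY)).bond
                    if rb is FREE:
                        unbinds.append(("unbind", i, s, False))
                        handled.add((i, s))
        # counter updates from rhs strings are provided via with_counters()
        self.actions = creates + list(dict.fromkeys(
            u for u in unbinds)) + deletes + sets + binds
        self._moved_endpoints = set(moves)

    def with_counters(self, *specs):
        """Attach counter updates, e.g. ``with_counters((1, "rna+=30"))``
        where the first element is the lhs agent index."""
        for i, spec in specs:
            parsed = _parse_counter_action(spec)
            if parsed is None:
                raise DefinitionError(f"bad counter action {spec!r}")
            name, op = parsed
            self.actions.append(("counter", i, name, op))
        return self

    # -- rendering -----------------------------------------------------
    def render(self):
        rhs_parts = []
        for ra in self.rhs_agents:
            rhs_parts.append("." if ra is None else ra.render())
        extra = [a for a in self.actions if a[0] == "counter"]
        txt = (f"'{self.name}' {self.lhs.render()} -> "
               f"{', '.join(rhs_parts)} @ '{self.rate_name}'")
        if extra:
            txt += " | " + ", ".join(f"{a[1]}.{a[2]}{'+=' if a[3][0]=='inc' else ':='}{a[3][1]}"
                                     for a in extra)
        return txt

    def footprint(self, signatures):
        """(sig, site) keys whose change can alter this rule's matches.

        For a shared bond label only the first endpoint is keyed: any
        event changing a bond touches both endpoints (a pure bond swap
        touches the partner side), so one key suffices; pattern order in
        the model places the anchor agent first.
        """
        keys = set()
        sigs = set()
        for i, pa in enumerate(self.lhs.agents):
            sigs.add(pa.sig_name)
            for s, sp in pa.sites.items():
                if sp.state is not None or sp.counter is not None or \
                        sp.bond is FREE or sp.bond is BOUND:
                    keys.add((pa.sig_name, s))
                if isinstance(sp.bond, int):
                    eps = self.lhs.labels[sp.bond]
                    if eps[0] == (i, s):
                        keys.add((pa.sig_name, s))
        return keys, sigs


class Model:
    """Signatures, rules and an initial-mixture spec."""

    def __init__(self, signatures, rules, initial_counts=None, init=None):
        self.signatures = {s.name: s for s in signatures}
        self.rules = list(rules)
        names = [r.name for r in self.rules]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise DefinitionError(f"duplicate rule names: {dup}")
        for r in self.rules:
            r.lhs.validate(self.signatures)
            for ra in r.rhs_agents:
                if ra is None:
                    continue
                sig = self.signatures.get(ra.sig_name)
                if sig is None:
                    raise DefinitionError(f"unknown signature {ra.sig_name!r}")
                for s, sp in ra.sites.items():
                    if sp.counter is not None:
                        if s not in sig.counters:
                            raise DefinitionError(
                                f"{ra.sig_name}.{s} is not a counter")
                    elif s not in sig.sites:
                        raise DefinitionError(
                            f"unknown site {ra.sig_name}.{s}")
                    elif sp.state is not None and sp.state not in sig.sites[s]:
                        raise DefinitionError(
                            f"state {sp.state!r} not allowed for "
                            f"{ra.sig_name}.{s}")
        self.initial_counts = dict(initial_counts or {})
        self._init = init             # optional callable(mixture) -> None
        self._compile()

    def _compile(self):
        self._key_to_rules = {}
        self._sig_to_rules = {}
        self._label_keyed = set()
        for idx, r in enumerate(self.rules):
            keys, sigs = r.footprint(self.signatures)
            for k in keys:
                self._key_to_rules.setdefault(k, []).append(idx)
            for sg in sigs:
                self._sig_to_rules.setdefault(sg, []).append(idx)
            for lab, eps in r.lhs.labels.items():
                i, s = eps[0]
                self._label_keyed.add((r.lhs.agents[i].sig_name, s))
            r._plan = _make_plan(r.lhs)

    def initial_mixture(self):
        m = Mixture(list(self.signatures.values()))
        for sig_name, count in self.initial_counts.items():
            for _ in range(int(count)):
                m.add_agent(sig_name)
        if self._init is not None:
            self._init(m)
        return m

    def render_rules(self):
        """Deterministic, name-sorted Kappa-like listing of every rule."""
        return "\n".join(r.render() for r in
                         sorted(self.rules, key=lambda r: r.name))


def apply_rule(rule, mixture, embedding, touched=None):
    """Apply ``rule`` at ``embedding`` (ids aligned with rule.lhs.agents).

    Mutates and returns the mixture; bond symmetry is preserved.  If
    ``touched`` is a set, the (sig, site) keys and signature names whose
    change may invalidate cached matches are added to it.
    """
    agents = mixture.agents
    for aid in embedding:
        if aid not in agents:
            raise ApplicationError(
                f"stale embedding for rule {rule.name!r}: agent {aid} gone")
    ids = list(embedding)             # extended by creations
    rec = touched if touched is not None else None
    moved = rule._moved_endpoints
    for act in rule.actions:
        op = act[0]
        if op == "set":
            _, i, s, v = act
            ag = agents[ids[i]]
            ag.states[s] = v
            if rec is not None:
                rec.add((ag.sig.name, s))
        elif op == "bind":
            _, i1, s1, i2, s2 = act
            a1, a2 = ids[i1], ids[i2]
            g1, g2 = agents[a1], agents[a2]
            for (g, s, pi) in ((g1, s1, (i1, s1)), (g2, s2, (i2, s2))):
                old = g.bonds.get(s)
                if old is not None:
                    if pi not in moved:
                        raise ApplicationError(
                            f"rule {rule.name!r}: bind to occupied "
                            f"{g.sig.name}.{s}")
                    pa, ps = old
                    agents[pa].bonds[ps] = None
                    g.bonds[s] = None
                    if rec is not None:
                        rec.add((agents[pa].sig.name, ps))
                        # a swapped endpoint stays bound: only key it if
                        # some rule anchors a bond label on it
                        if pi in moved and (g.sig.name, s) in \
                                getattr(mixture, "_label_keyed", ()):
                            rec.add((g.sig.name, s))
            g1.bonds[s1] = (a2, s2)
            g2.bonds[s2] = (a1, s1)
            if rec is not None:
                if (i1, s1) not in moved:
                    rec.add((g1.sig.name, s1))
                if (i2, s2) not in moved:
                    rec.add((g2.sig.name, s2))
        elif op == "unbind":
            _, i, s, partner_moved = act
            ag = agents[ids[i]]
            if ag.bonds.get(s) is None:
                raise ApplicationError(
                    f"rule {rule.name!r}: unbind of free {ag.sig.name}.{s}")
            pa, ps = mixture.unbind(ids[i], s)
            if rec is not None:
                rec.add((ag.sig.name, s))
                pkey = (agents[pa].sig.name, ps)
                # a partner that is immediately rebound by this rule stays
                # bound; only bond-label anchors on it need invalidation
                if not partner_moved or pkey in \
                        getattr(mixture, "_label_keyed", ()):
                    rec.add(pkey)
        elif op == "create":
            _, j, sig_name, states, counters = act
            ag = mixture.add_agent(sig_name, states, counters)
            while len(ids) <= j:
                ids.append(None)
            ids[j] = ag.id
            if rec is not None:
                rec.add(sig_name)
        elif op == "delete":
            _, i = act
            ag = agents.get(ids[i])
            if ag is None:
                raise ApplicationError(f"rule {rule.name!r}: double delete")
            if rec is not None:
                for s, b in ag.bonds.items():
                    if b is not None:
                        rec.add((agents[b[0]].sig.name, b[1]))
                rec.add(ag.sig.name)
            mixture.remove_agent(ids[i])
        elif op == "counter":
            _, i, name, (kind, v) = act
            ag = agents[ids[i]]
            ag.counters[name] = v if kind == "set" else ag.counters[name] + v
            if rec is not None:
                rec.add((ag.sig.name, name))
        else:  # pragma: no cover
            raise ApplicationError(f"unknown action {op!r}")
    mixture.event_count += 1
    return mixture


# ----------------------------------------------------------------------
# Simulation
# ----------------------------------------------------------------------

@dataclass
class Trajectory:
    """One stochastic run: aligned observable snapshots plus event log."""
    seed: int
    times: np.ndarray
    values: np.ndarray                # (n_times, n_observables)
    columns: list
    events: list = field(default_factory=list)   # (time, rule name)
    final_mixture: Mixture | None = None
    n_events: int = 0


def simulate(model, t_max, seed, observable_times, observe=None,
             observables=None, log_rules=None, validate_every=0,
             mixture=None):
    """Exact Gillespie direct-method simulation of ``model``.

    Observables are recorded at the requested wall-clock times with the
    state after the last event at or before each time.  ``observe`` is a
    callable(mixture) -> sequence; alternatively ``observables`` is a
    list of (name, Pattern) counted by embedding.  ``log_rules`` (a set
    of names, or True for all) enables the event log.  If all
    propensities vanish before ``t_max`` the final state is recorded at
    the remaining observable times.
    """
    if t_max <= 0:
        raise DefinitionError("t_max must be positive")
    mix = model.initial_mixture() if mixture is None else mixture
    mix._label_keyed = model._label_keyed
    if observe is None:
        if observables is None:
            observables = [(name, Pattern([A(name)]))
                           for name in model.signatures]
        cols = [name for name, _ in observables]
        pats = [p for _, p in observables]
        for p in pats:
            p.validate(model.signatures)

        def observe(m):
            return [len(_match(p, m)) for p in pats]
    else:
        cols = list(getattr(observe, "columns", [])) or None

    rng = np.random.default_rng(seed)
    rules = model.rules
    n_rules = len(rules)
    emb = [None] * n_rules
    prop = np.zeros(n_rules)
    dirty = set(range(n_rules))
    key_map = model._key_to_rules
    sig_map = model._sig_to_rules

    obs_times = np.asarray(sorted(observable_times), dtype=float)
    n_obs = len(obs_times)
    values = []
    times_rec = []
    k = 0
    events = []
    log_all = log_rules is True
    log_set = set() if log_rules in (None, True) else set(log_rules)
    t = mix.time
    check = int(validate_every)

    def record_upto(limit, inclusive):
        nonlocal k
        while k < n_obs and (obs_times[k] < limit or
                             (inclusive and obs_times[k] <= limit)):
            times_rec.append(obs_times[k])
            values.append(observe(mix))
            k += 1

    while True:
        for ridx in dirty:
            r = rules[ridx]
            emb[ridx] = _match(r.lhs, mix, r._plan)
            prop[ridx] = r.rate * len(emb[ridx])
        dirty.clear()
        total = float(prop.sum())
        if total <= 0.0:
            record_upto(t_max, inclusive=True)
            break
        dt = -math.log(rng.random()) / total
        t_next = t + dt
        if t_next > t_max:
            record_upto(t_max, inclusive=True)
            t = t_max
            break
        record_upto(t_next, inclusive=False)
        # rule choice
        x = rng.random() * total
        acc = 0.0
        ridx = n_rules - 1
        for i in range(n_rules):
            acc += prop[i]
            if x < acc:
                ridx = i
                break
        embs = emb[ridx]
        j = int(rng.random() * len(embs))
        if j == len(embs):            # guard against fp edge
            j -= 1
        rule = rules[ridx]
        touched = set()
        apply_rule(rule, mix, embs[j], touched)
        t = t_next
        mix.time = t
        if log_all or rule.name in log_set:
            events.append((t, rule.name))
        for key in touched:
            if isinstance(key, tuple):
                for ri in key_map.get(key, ()):
                    dirty.add(ri)
            else:
                for ri in sig_map.get(key, ()):
                    dirty.add(ri)
        if check and mix.event_count % check == 0:
            mix.validate()
    mix.time = t
    vals = np.asarray(values, dtype=float) if values else \
        np.zeros((0, 0))
    if cols is None:
        cols = [f"obs{i}" for i in range(vals.shape[1] if vals.size else 0)]
    return Trajectory(seed=seed, times=np.asarray(times_rec),
                      values=vals, columns=cols, events=events,
                      final_mixture=mix, n_events=mix.event_count)


def run_ensemble(model, n_runs, t_max, base_seed, observable_times,
                 **kwargs):
    """Independent trajectories with seeds ``base_seed + i``, in order."""
    if n_runs < 1:
        raise DefinitionError("n_runs must be >= 1")
    return [simulate(model, t_max, base_seed + i, observable_times, **kwargs)
            for i in range(n_runs)]


# ----------------------------------------------------------------------
# Brute-force CTMC oracle (for small reachable state spaces)
# ----------------------------------------------------------------------

def enumerate_ctmc(model, max_states=200):
    """Explicitly construct the CTMC of a model's reachable state space.

    Breadth-first enumeration from the initial mixture; per-embedding
    rule application generates transitions at the rule's rate.  Returns
    (states, index_of_initial, Q) where Q is the dense generator matrix.
    Raises DefinitionError if more than ``max_states`` states are found.
    """
    init = model.initial_mixture()
    index = {init.canonical(): 0}
    store = [init]
    edges = []                         # (i, j, rate)
    frontier = [0]
    while frontier:
        i = frontier.pop()
        mix = store[i]
        for rule in model.rules:
            embs = _match(rule.lhs, mix)
            for e in embs:
                nxt = mix.copy()
                apply_rule(rule, nxt, e)
                key = nxt.canonical()
                j = index.get(key)
                if j is None:
                    j = len(store)
                    if j >= max_states:
                        raise DefinitionError(
                            f"state space exceeds {max_states}")
                    index[key] = j
                    store.append(nxt)
                    frontier.append(j)
                edges.append((i, j, rule.rate))
    n = len(store)
    Q = np.zeros((n, n))
    for i, j, rate in edges:
        if i != j:
            Q[i, j] += rate
    for i in range(n):
        Q[i, i] = -Q[i].sum()
    return store, 0, Q


# ----------------------------------------------------------------------
# TSV export
# ----------------------------------------------------------------------

def trajectory_to_tsv(traj, path):
    """Snapshot table: ``time<TAB>observable1<TAB>...``."""
    with open(path, "w") as fh:
        fh.write("time\t" + "\t".join(traj.columns) + "\n")
        for t, row in zip(traj.times, traj.values):
            fh.write(f"{t:.6g}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def events_to_tsv(traj, path):
    """Event log: ``time<TAB>rule_name``."""
    with open(path, "w") as fh:
        fh.write("time\trule_name\n")
        for t, name in traj.events:
            fh.write(f"{t:.6g}\t{name}\n")
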