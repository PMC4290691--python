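"""Reduced ordered binary decision diagrams.

A small self-contained ROBDD manager used as the canonical set
representation of the symbolic engine.  Nodes are interned integers;
``0`` and ``1`` are the terminal constants.  Variables are identified by
their position in the global order (smaller index = nearer the root).

Only the operations the checker needs are provided: ``ite`` (from which
the Boolean connectives derive) and simultaneous substitution
(``compose``), which implements functional image computation without
ever building a monolithic transition relation.
"""

from __future__ import annotations

import sys
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

FALSE = 0
TRUE = 1


class BDD:
    """Manager owning the shared node store for one variable order."""

    ITE_CACHE_CAP = 1_000_000

    def __init__(self, nvars: int):
        self.nvars = nvars
        # node id -> (var, lo, hi); slots 0/1 are placeholders for terminals
        self._var: List[int] = [nvars, nvars]
        self._lo: List[int] = [0, 1]
        self._hi: List[int] = [0, 1]
        self._unique: Dict[tuple, int] = {}
        self._ite_cache: Dict[tuple, int] = {}
        if sys.getrecursionlimit() < 10000:
            sys.setrecursionlimit(10000)

    # -- node store ---------------------------------------------------

    def _mk(self, var: int, lo: int, hi: int) -> int:
        if lo == hi:
            return lo
        key = (var, lo, hi)
        u = self._unique.get(key)
        if u is None:
            u = len(self._var)
            self._var.append(var)
            self._lo.append(lo)
            self._hi.append(hi)
            self._unique[key] = u
        return u

    def copy_roots(self, roots: Iterable[int]) -> Tuple["BDD", Dict[int, int]]:
        """A fresh manager holding only the nodes reachable from roots.

        Returns the new manager and the old-id -> new-id map for the
        requested roots (garbage collection by copying).
        """
        new = BDD(self.nvars)
        memo = {FALSE: FALSE, TRUE: TRUE}

        def rec(u: int) -> int:
            r = memo.get(u)
            if r is None:
                r = new._mk(self._var[u], rec(self._lo[u]), rec(self._hi[u]))
                memo[u] = r
            return r

        return new, {r: rec(r) for r in set(roots)}

    def var(self, i: int) -> int:
        """The literal x_i."""
        if not 0 <= i < self.nvars:
            raise ValueError(f"variable index {i} out of range")
        return self._mk(i, FALSE, TRUE)

    def top_var(self, u: int) -> int:
        return self._var[u]

    def size(self) -> int:
        return len(self._var)

    # -- core connectives ---------------------------------------------

    def ite(self, f: int, g: int, h: int) -> int:
        if f == TRUE:
            return g
        if f == FALSE:
            return h
        if g == h:
            return g
        if g == TRUE and h == FALSE:
            return f
        key = (f, g, h)
        r = self._ite_cache.get(key)
        if r is not None:
            return r
        v = min(self._var[f], self._var[g], self._var[h])
        fl, fh = self._cof(f, v)
        gl, gh = self._cof(g, v)
        hl, hh = self._cof(h, v)
        hi = self.ite(fh, gh, hh)
        lo = self.ite(fl, gl, hl)
        r = self._mk(v, lo, hi)
        if len(self._ite_cache) > self.ITE_CACHE_CAP:
            self._ite_cache.clear()
        self._ite_cache[key] = r
        return r

    def _cof(self, u: int, v: int):
        if self._var[u] == v:
            return self._lo[u], self._hi[u]
        return u, u

    def apply_not(self, f: int) -> int:
        return self.ite(f, FALSE, TRUE)

    def apply_and(self, f: int, g: int) -> int:
        return self.ite(f, g, FALSE)

    def apply_or(self, f: int, g: int) -> int:
        return self.ite(f, TRUE, g)

    def apply_diff(self, f: int, g: int) -> int:
        """f AND NOT g."""
        return self.ite(g, FALSE, f)

    def apply_imp(self, f: int, g: int) -> int:
        return self.ite(f, g, TRUE)

    def conj(self, fs: Iterable[int]) -> int:
        r = TRUE
        for f in fs:
            r = self.apply_and(r, f)
        return r

    def disj(self, fs: Iterable[int]) -> int:
        r = FALSE
        for f in fs:
            r = self.apply_or(r, f)
        return r

    # -- substitution -------------------------------------------------

    def compose(self, u: int, sub: Mapping[int, int]) -> int:
        """Simultaneous substitution of variables by BDDs.

        ``sub`` maps variable indices to replacement functions; variables
        not in the map are left alone.  Replacements may mention any
        variable, including ones ordered above the substituted variable.
        """
        if not sub:
            return u
        maxkey = max(sub)
        cache: Dict[int, int] = {}

        def rec(w: int) -> int:
            if w <= TRUE or self._var[w] > maxkey:
                return w
            r = cache.get(w)
            if r is not None:
                return r
            v = self._var[w]
            rlo = rec(self._lo[w])
            rhi = rec(self._hi[w])
            g = sub.get(v)
            if g is None:
                # substituted functions may introduce variables ordered
                # above v, so rebuild through ite rather than _mk
                r = self.ite(self.var(v), rhi, rlo)
            else:
                r = self.ite(g, rhi, rlo)
            cache[w] = r
            return r

        return rec(u)

    def cofactor(self, u: int, assignment: Mapping[int, bool]) -> int:
        return self.compose(u, {v: (TRUE if b else FALSE) for v, b in assignment.items()})

    def exist(self, variables: Iterable[int], u: int) -> int:
        """Existential quantification over the given variables."""
        vs = frozenset(variables)
        if not vs:
            return u
        maxv = max(vs)
        cache: Dict[int, int] = {}

        def rec(w: int) -> int:
            if w <= TRUE or self._var[w] > maxv:
                return w
            r = cache.get(w)
            if r is not None:
                return r
            v = self._var[w]
            rlo = rec(self._lo[w])
            rhi = rec(self._hi[w])
            if v in vs:
                r = self.apply_or(rlo, rhi)
            else:
                r = self._mk(v, rlo, rhi)
            cache[w] = r
            return r

        return rec(u)

    # -- evaluation / enumeration -------------------------------------

    def eval(self, u: int, bits: Sequence[bool]) -> bool:
        while u > TRUE:
            u = self._hi[u] if bits[self._var[u]] else self._lo[u]
        return u == TRUE

    def pick(self, u: int) -> Optional[Dict[int, bool]]:
        """One satisfying assignment (lo-branch preferred), or None.

        Variables not mentioned are unconstrained (may take either value).
        """
        if u == FALSE:
            return None
        out: Dict[int, bool] = {}
        while u > TRUE:
            if self._lo[u] != FALSE:
                out[self._var[u]] = False
                u = self._lo[u]
            else:
                out[self._var[u]] = True
                u = self._hi[u]
        return out

    def support(self, u: int) -> set:
        seen = set()
        out = set()
        stack = [u]
        while stack:
            w = stack.pop()
            if w <= TRUE or w in seen:
                continue
            seen.add(w)
            out.add(self._var[w])
            stack.append(self._lo[w])
            stack.append(self._hi[w])
        return out

    def count(self, u: int, nvars: Optional[int] = None) -> int:
        """Number of satisfying assignments over ``nvars`` variables."""
        n = self.nvars if nvars is None else nvars
        cache: Dict[int, int] = {}

        def level(w: int) -> int:
            return n if w <= TRUE else self._var[w]

        def rec(w: int) -> int:
            if w == FALSE:
                return 0
            if w == TRUE:
                return 1
            r = cache.get(w)
            if r is None:
                lo, hi = self._lo[w], self._hi[w]
                v = self._var[w]
                r = (rec(lo) << (level(lo) - v - 1)) + (rec(hi) << (level(hi) - v - 1))
                cache[w] = r
            return r

        return rec(u) << level(u)
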