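"""Minimum-free-energy RNA secondary structure prediction.

A self-contained, simplified Zuker-style dynamic program over a
nearest-neighbour energy model: stacking energies for the six canonical
pairs (Watson-Crick plus G:U wobble), length-indexed hairpin / bulge /
internal-loop penalties, and an affine multiloop term.  No dangling ends,
no coaxial stacking, 37 degC only.  The model aims for qualitative Mfold-like
behaviour (correct MFE sign, correct hairpin topology on clean stem-loops),
not for matching published Turner energies digit-for-digit.

The energy of a complete structure decomposes over the loops closed by each
pair; :func:`structure_energy` evaluates that decomposition for an arbitrary
nested pair set, and the DP in :func:`fold_mfe` minimises the same quantity,
so exhaustive enumeration over all structures is a valid independent oracle.

MFEI — the minimal free energy index used to separate miRNA precursors from
other transcripts — is ``|MFE| / length * 100 / GC%``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


INF = 1e9
MIN_HAIRPIN = 3  # minimum unpaired bases in a hairpin loop

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
# pair type indices: AU UA CG GC GU UG, -1 if not pairable
_PAIR_INDEX = -np.ones((4, 4), dtype=np.int64)
for _k, (_a, _b) in enumerate([(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]):
    _PAIR_INDEX[_a, _b] = _k

# Turner-like stacking energies (kcal/mol) for stack of pair p1=(i,j) on
# p2=(i+1,j-1); rows/cols in pair-index order AU UA CG GC GU UG.
_STACK = np.array(
    [
        [-0.9, -1.1, -2.2, -2.1, -0.6, -1.4],
        [-1.3, -0.9, -2.4, -2.1, -1.0, -1.3],
        [-2.1, -2.1, -3.3, -2.4, -1.4, -2.1],
        [-2.4, -2.2, -3.4, -3.3, -1.5, -2.5],
        [-1.3, -1.4, -2.5, -2.1, -0.5, 1.3],
        [-1.0, -0.6, -2.1, -1.4, -0.3, -0.5],
    ]
)

_RT_COEF = 1.75 * 0.001987 * 310.15  # Jacobson-Stockmayer extrapolation slope

_HAIRPIN_TAB = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_TAB = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL_TAB = {2: 1.5, 3: 1.8, 4: 2.0, 5: 2.2, 6: 2.5}


def _loop_array(tab: dict, n: int) -> np.ndarray:
    """Length-indexed loop penalty array with log extrapolation past the table."""
    arr = np.full(n + 1, INF)
    mx = max(tab)
    for size in range(1, n + 1):
        if size in tab:
            arr[size] = tab[size]
        elif size > mx:
            arr[size] = tab[mx] + _RT_COEF * np.log(size / mx)
    return arr


@dataclass
class EnergyModel:
    """Auditable container for every constant the folding DP consumes.

    ``pair_bonus`` is an additive per-pair term (0 in the default model); with
    all loop penalties and stacks zeroed and ``pair_bonus=-1`` the model
    degenerates to Nussinov base-pair maximisation, which the tests exploit.
    ``max_interior`` caps the unpaired span of interior loops considered by
    the DP (``None`` = unlimited).
    """

    stack: np.ndarray = field(default_factory=lambda: _STACK.copy())
    hairpin_tab: dict = field(default_factory=lambda: dict(_HAIRPIN_TAB))
    bulge_tab: dict = field(default_factory=lambda: dict(_BULGE_TAB))
    internal_tab: dict = field(default_factory=lambda: dict(_INTERNAL_TAB))
    multi_close: float = 3.4
    multi_branch: float = 0.4
    multi_unpaired: float = 0.1
    pair_bonus: float = 0.0
    max_interior: int | None = 30

    def loop_arrays(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            _loop_array(self.hairpin_tab, n),
            _loop_array(self.bulge_tab, n),
            _loop_array(self.internal_tab, n),
        )

    @classmethod
    def nussinov(cls) -> "EnergyModel":
        """Degenerate model: every allowed pair worth -1, no loop penalties."""
        z = {s: 0.0 for s in range(1, 31)}
        z3 = {s: 0.0 for s in range(3, 31)}
        return cls(
            stack=np.zeros((6, 6)),
            hairpin_tab=z3,
            bulge_tab=dict(z),
            internal_tab={s: 0.0 for s in range(2, 31)},
            multi_close=0.0,
            multi_branch=0.0,
            multi_unpaired=0.0,
            pair_bonus=-1.0,
            max_interior=None,
        )


DEFAULT_MODEL = EnergyModel()


def encode(seq: str) -> np.ndarray:
    """Encode an ACGU/T sequence as int codes; reject other characters."""
    try:
        return np.array([_BASE_CODE[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from exc


def pair_type(a: int, b: int) -> int:
    return int(_PAIR_INDEX[a, b])


def can_pair(seq_code: np.ndarray, i: int, j: int) -> bool:
    return _PAIR_INDEX[seq_code[i], seq_code[j]] >= 0 and j - i - 1 >= MIN_HAIRPIN


@njit(cache=False)
def _fill(codes, pidx, stack, hp, bp, ip, ma, mb, mc, bonus, max_int):  # pragma: no cover - numba
    n = codes.shape[0]
    V = np.full((n, n), INF)
    M = np.full((n, n), INF)   # >=1 multiloop branches in [i,j]
    M2 = np.full((n, n), INF)  # >=2 multiloop branches in [i,j]
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            pt = pidx[codes[i], codes[j]]
            if pt >= 0:
                best = hp[j - i - 1]
                # interior loops / bulges / stacks
                max_u = j - i - 2 - (MIN_HAIRPIN + 1)
                if max_int >= 0 and max_int < max_u:
                    max_u = max_int
                for p in range(i + 1, j - 1):
                    u1 = p - i - 1
                    if u1 > max_u:
                        break
                    for q in range(j - 1, p + MIN_HAIRPIN, -1):
                        u2 = j - q - 1
                        if u1 + u2 > max_u:
                            break
                        pt2 = pidx[codes[p], codes[q]]
                        if pt2 < 0 or V[p, q] >= INF:
                            continue
                        if u1 == 0 and u2 == 0:
                            cost = stack[pt, pt2]
                        elif u1 == 0 or u2 == 0:
                            cost = bp[u1 + u2]
                        else:
                            cost = ip[u1 + u2]
                        cand = cost + V[p, q]
                        if cand < best:
                            best = cand
                # multiloop closed by (i, j)
                if M2[i + 1, j - 1] < INF:
                    cand = ma + mb + M2[i + 1, j - 1]
                    if cand < best:
                        best = cand
                V[i, j] = best + bonus
        for i in range(0, n - span):
            j = i + span
            # M: at least one branch
            best = INF
            if M[i + 1, j] < INF:
                best = M[i + 1, j] + mc
            if M[i, j - 1] < INF and M[i, j - 1] + mc < best:
                best = M[i, j - 1] + mc
            if V[i, j] < INF and V[i, j] + mb < best:
                best = V[i, j] + mb
            b2 = INF
            if M2[i + 1, j] < INF:
                b2 = M2[i + 1, j] + mc
            for k in range(i + MIN_HAIRPIN + 1, j):
                if V[i, k] < INF and M[k + 1, j] < INF:
                    cand = V[i, k] + mb + M[k + 1, j]
                    if cand < best:
                        best = cand
                    if cand < b2:
                        b2 = cand
            M[i, j] = best
            M2[i, j] = b2
    # external loop
    W = np.zeros(n)
    for j in range(1, n):
        best = W[j - 1]
        for i in range(0, j):
            if V[i, j] < INF:
                left = W[i - 1] if i > 0 else 0.0
                if left + V[i, j] < best:
                    best = left + V[i, j]
        W[j] = best
    return V, M, M2, W


class _Tables:
    """Filled DP matrices plus the scalar constants, for traceback."""

    def __init__(self, codes, model: EnergyModel):
        n = len(codes)
        hp, bp, ip = model.loop_arrays(max(n, MIN_HAIRPIN + 1))
        max_int = -1 if model.max_interior is None else model.max_interior
        self.codes = codes
        self.model = model
        self.hp, self.bp, self.ip = hp, bp, ip
        self.V, self.M, self.M2, self.W = _fill(
            codes,
            _PAIR_INDEX,
            np.asarray(model.stack, dtype=np.float64),
            hp,
            bp,
            ip,
            model.multi_close,
            model.multi_branch,
            model.multi_unpaired,
            model.pair_bonus,
            max_int,
        )


_EPS = 1e-7


def _traceback(t: _Tables) -> list[tuple[int, int]]:
    """Deterministic traceback; ties broken by a fixed case order
    (hairpin, then interior by increasing (u1, u2), then multiloop)."""
    codes, m = t.codes, t.model
    n = len(codes)
    pairs: list[tuple[int, int]] = []
    stack_jobs: list[tuple[str, int, int]] = [("W", 0, n - 1)]
    while stack_jobs:
        kind, i, j = stack_jobs.pop()
        if j <= i:
            continue
        if kind == "W":
            if abs(t.W[j] - (t.W[j - 1] if j > 0 else 0.0)) < _EPS:
                stack_jobs.append(("W", i, j - 1))
                continue
            done = False
            for p in range(0, j):
                left = t.W[p - 1] if p > 0 else 0.0
                if t.V[p, j] < INF and abs(t.W[j] - (left + t.V[p, j])) < _EPS:
                    stack_jobs.append(("V", p, j))
                    if p > 0:
                        stack_jobs.append(("W", 0, p - 1))
                    done = True
                    break
            if not done:  # numerical safety net
                stack_jobs.append(("W", i, j - 1))
        elif kind == "V":
            pairs.append((i, j))
            target = t.V[i, j] - m.pair_bonus
            pt = pair_type(codes[i], codes[j])
            if abs(target - t.hp[j - i - 1]) < _EPS:
                continue
            max_u = j - i - 2 - (MIN_HAIRPIN + 1)
            if m.max_interior is not None:
                max_u = min(max_u, m.max_interior)
            found = False
            for p in range(i + 1, j - 1):
                u1 = p - i - 1
                if u1 > max_u:
                    break
                for q in range(j - 1, p + MIN_HAIRPIN, -1):
                    u2 = j - q - 1
                    if u1 + u2 > max_u:
                        break
                    pt2 = pair_type(codes[p], codes[q])
                    if pt2 < 0 or t.V[p, q] >= INF:
                        continue
                    if u1 == 0 and u2 == 0:
                        cost = m.stack[pt, pt2]
                    elif u1 == 0 or u2 == 0:
                        cost = t.bp[u1 + u2]
                    else:
                        cost = t.ip[u1 + u2]
                    if abs(target - (cost + t.V[p, q])) < _EPS:
                        stack_jobs.append(("V", p, q))
                        found = True
                        break
                if found:
                    break
            if not found:
                stack_jobs.append(("M2", i + 1, j - 1))
        elif kind == "M":
            if t.V[i, j] < INF and abs(t.M[i, j] - (t.V[i, j] + m.multi_branch)) < _EPS:
                stack_jobs.append(("V", i, j))
                continue
            if abs(t.M[i, j] - (t.M[i + 1, j] + m.multi_unpaired)) < _EPS:
                stack_jobs.append(("M", i + 1, j))
                continue
            if abs(t.M[i, j] - (t.M[i, j - 1] + m.multi_unpaired)) < _EPS:
                stack_jobs.append(("M", i, j - 1))
                continue
            for k in range(i + MIN_HAIRPIN + 1, j):
                if t.V[i, k] < INF and t.M[k + 1, j] < INF and abs(
                    t.M[i, j] - (t.V[i, k] + m.multi_branch + t.M[k + 1, j])
                ) < _EPS:
                    stack_jobs.append(("V", i, k))
                    stack_jobs.append(("M", k + 1, j))
                    break
        else:  # M2
            if abs(t.M2[i, j] - (t.M2[i + 1, j] + m.multi_unpaired)) < _EPS:
                stack_jobs.append(("M2", i + 1, j))
                continue
            for k in range(i + MIN_HAIRPIN + 1, j):
                if t.V[i, k] < INF and t.M[k + 1, j] < INF and abs(
                    t.M2[i, j] - (t.V[i, k] + m.multi_branch + t.M[k + 1, j])
                ) < _EPS:
                    stack_jobs.append(("V", i, k))
                    stack_jobs.append(("M", k + 1, j))
                    break
    return sorted(pairs)


@dataclass
class HairpinStructure:
    """A folded sequence: nested pair set, MFE and the derived indices."""

    sequence: str
    pairs: list[tuple[int, int]]
    mfe: float
    gc_fraction: float
    mfei: float

    @property
    def dot_bracket(self) -> str:
        return render_dot_bracket(len(self.sequence), self.pairs)

    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s) if s else 0.0


def mfei(mfe: float, length: int, gc: float) -> float:
    """Minimal free energy index: |MFE|/length*100 divided by GC percentage."""
    if length <= 0:
        raise ValueError("length must be positive")
    if gc <= 0:
        raise ValueError("MFEI undefined for GC fraction 0")
    return abs(mfe) / length * 100.0 / (gc * 100.0)


def fold_mfe(seq: str, model: EnergyModel | None = None) -> HairpinStructure:
    """Globally optimal nested structure of ``seq`` under ``model``.

    Raises ``ValueError`` on non-ACGU/T input. Sequences shorter than the
    minimum hairpin cannot pair and fold to the open chain at 0 kcal/mol.
    """
    model = model or DEFAULT_MODEL
    codes = encode(seq)
    n = len(codes)
    gc = gc_fraction(seq)
    if n < MIN_HAIRPIN + 2:
        return HairpinStructure(seq, [], 0.0, gc, 0.0)
    t = _Tables(codes, model)
    e = float(t.W[n - 1])  # W[j] = min(W[j-1], ...) from 0, hence always <= 0
    if e >= -1e-12:
        pairs: list[tuple[int, int]] = []
        e = 0.0
    else:
        pairs = _traceback(t)
    idx = mfei(e, n, gc) if gc > 0 else 0.0
    return HairpinStructure(seq, pairs, e, gc, idx)


def structure_energy(seq: str, pairs: Iterable[tuple[int, int]],
                     model: EnergyModel | None = None) -> float:
    """Energy of an explicit nested structure under the same decomposition
    the DP minimises: each pair closes a hairpin, stack/bulge/interior loop
    or multiloop; the exterior loop is free."""
    model = model or DEFAULT_MODEL
    codes = encode(seq)
    n = len(codes)
    plist = sorted(pairs)
    hp, bp, ip = model.loop_arrays(max(n, MIN_HAIRPIN + 1))
    partner = {}
    for i, j in plist:
        if pair_type(codes[i], codes[j]) < 0:
            raise ValueError(f"({i},{j}) is not a pairable combination")
        partner[i] = j
        partner[j] = i
    energy = 0.0
    for (i, j) in plist:
        energy += model.pair_bonus
        # scan the loop closed by (i, j)
        branches = []
        unpaired = 0
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                branches.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        if not branches:
            energy += hp[j - i - 1]
        elif len(branches) == 1:
            p, q = branches[0]
            u1, u2 = p - i - 1, j - q - 1
            if u1 == 0 and u2 == 0:
                energy += model.stack[pair_type(codes[i], codes[j]),
                                      pair_type(codes[p], codes[q])]
            elif u1 == 0 or u2 == 0:
                energy += bp[u1 + u2]
            else:
                energy += ip[u1 + u2]
        else:
            energy += (model.multi_close
                       + model.multi_branch * (len(branches) + 1)
                       + model.multi_unpaired * unpaired)
    return energy


def render_dot_bracket(n: int, pairs: Iterable[tuple[int, int]]) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i] = "("
        out[j] = ")"
    return "".join(out)


def parse_dot_bracket(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for k, c in enumerate(db):
        if c == "(":
            stack.append(k)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), k))
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def hairpin_loops(pairs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Closing pairs of hairpin loops (pairs with no pair nested inside)."""
    loops = []
    ps = sorted(pairs)
    for i, j in ps:
        if not any(i < a and b < j for a, b in ps):
            loops.append((i, j))
    return loops


def longest_stem(pairs: Sequence[tuple[int, int]]) -> int:
    """Length of the longest run of directly stacked pairs."""
    pset = set(map(tuple, pairs))
    best = 0
    for i, j in pset:
        if (i - 1, j + 1) in pset:
            continue  # not a stack start
        run = 1
        a, b = i + 1, j - 1
        while (a, b) in pset:
            run += 1
            a, b = a + 1, b - 1
        best = max(best, run)
    return best


def n_hairpin_loops(structure: HairpinStructure) -> int:
    return len(hairpin_loops(structure.pairs))


def classify_arm(structure: HairpinStructure, start: int, end: int) -> str:
    """Locate ``[start, end)`` relative to the (single) hairpin of a structure:
    ``5p`` / ``3p`` arm, ``loop``, or ``outside`` the folded hairpin span."""
    loops = hairpin_loops(structure.pairs)
    if len(loops) != 1:
        raise ValueError("arm classification requires exactly one hairpin loop")
    hi, hj = loops[0]
    if not structure.pairs:
        return "outside"
    lo = min(i for i, _ in structure.pairs)
    hi_out = max(j for _, j in structure.pairs)
    if start > hi and end <= hj:
        return "loop"
    if start >= lo and end <= hi + 1:
        return "5p"
    if start >= hj and end <= hi_out + 1:
        return "3p"
    return "outside"


def hairpin_features(structure: HairpinStructure) -> dict:
    """Summary used by the discovery gate: loop count and longest stem."""
    return {
        "n_hairpin_loops": n_hairpin_loops(structure),
        "longest_stem": longest_stem(structure.pairs),
    }
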