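"""Temperature-dependent RNA secondary-structure thermodynamics.

A minimum-free-energy dynamic program over a compact nearest-neighbour
model: Watson-Crick and wobble stacks carry enthalpy/entropy terms so
stack free energies scale as dH - T*dS; loop penalties are treated as
purely entropic and scale linearly with temperature. The model is a
deliberately simplified stand-in for full Turner parameter sets:
absolute energies are not comparable with reference folders, but
orderings and distribution shifts are.

No pseudoknots, coaxial stacking or dangling ends; internal/bulge loops
are capped at 30 unpaired bases; hairpin loops have >= 3 unpaired bases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from editscan.genome import Genome, revcomp
from editscan.stats import star_label

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap(args[0]) if args and callable(args[0]) else wrap


REFERENCE_T = 310.15  # K; tabulated loop penalties refer to this temperature
GAS_CONSTANT = 0.0019872  # kcal/mol/K
_INF = 1e18

# base encoding for folding: A C G U (T folds as U), anything else = 4 (N)
_FOLD_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_PAIR_TYPES = ["AU", "UA", "CG", "GC", "GU", "UG"]
_PAIR_INDEX = {p: i for i, p in enumerate(_PAIR_TYPES)}

# Watson-Crick stack parameters, keyed (outer pair, inner pair) where the
# outer pair is (seq[i], seq[j]) and the inner (seq[i+1], seq[j-1]).
# Values: (dG at 310.15 K, dH), kcal/mol.
_WC_STACKS: Dict[Tuple[str, str], Tuple[float, float]] = {
    ("AU", "AU"): (-0.93, -6.82),
    ("AU", "UA"): (-1.10, -9.38),
    ("UA", "AU"): (-1.33, -7.69),
    ("CG", "UA"): (-2.08, -10.48),
    ("CG", "AU"): (-2.11, -10.44),
    ("GC", "UA"): (-2.24, -11.40),
    ("GC", "AU"): (-2.35, -12.44),
    ("CG", "GC"): (-2.36, -10.64),
    ("GC", "GC"): (-3.26, -13.39),
    ("GC", "CG"): (-3.42, -14.88),
}
_GU_STACK = (-1.00, -8.00)  # uniform wobble-stack stand-in


def _mirror(pair: str) -> str:
    return pair[::-1]


def _build_stack_tables() -> Tuple[np.ndarray, np.ndarray]:
    """(dH, dS) arrays indexed [outer pair type, inner pair type]."""
    dh = np.zeros((6, 6))
    ds = np.zeros((6, 6))
    for outer in _PAIR_TYPES:
        for inner in _PAIR_TYPES:
            key = (outer, inner)
            if key in _WC_STACKS:
                g37, h = _WC_STACKS[key]
            elif (_mirror(inner), _mirror(outer)) in _WC_STACKS:
                g37, h = _WC_STACKS[(_mirror(inner), _mirror(outer))]
            else:
                g37, h = _GU_STACK
            dh[_PAIR_INDEX[outer], _PAIR_INDEX[inner]] = h
            ds[_PAIR_INDEX[outer], _PAIR_INDEX[inner]] = (h - g37) / REFERENCE_T
    return dh, ds


@dataclass
class EnergyModel:
    """Compact nearest-neighbour energy model with temperature dependence.

    Stack terms carry (dH, dS) so dG(T) = dH - T*dS; loop initiation
    penalties are tabulated at 310.15 K and scaled by T/310.15 (purely
    entropic approximation). Sizes beyond the tables extrapolate
    logarithmically with 1.75*R*T_ref*ln(size/max_tabulated).
    """

    stack_dh: np.ndarray = field(default_factory=lambda: _build_stack_tables()[0])
    stack_ds: np.ndarray = field(default_factory=lambda: _build_stack_tables()[1])
    hairpin_init: Dict[int, float] = field(
        default_factory=lambda: {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
    )
    bulge_init: Dict[int, float] = field(
        default_factory=lambda: {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
    )
    internal_init: Dict[int, float] = field(
        default_factory=lambda: {2: 1.5, 3: 1.6, 4: 1.7, 5: 1.8, 6: 2.0}
    )
    multiloop_offset: float = 3.4
    multiloop_branch: float = 0.4
    multiloop_unpaired: float = 0.1
    min_hairpin_loop: int = 3
    max_internal: int = 30

    def stack_energy(self, outer: int, inner: int, temperature: float) -> float:
        return self.stack_dh[outer, inner] - temperature * self.stack_ds[outer, inner]

    def _loop_table(self, table: Dict[int, float], size: int) -> float:
        if size in table:
            return table[size]
        largest = max(table)
        return table[largest] + 1.75 * GAS_CONSTANT * REFERENCE_T * np.log(size / largest)

    def _scale(self, temperature: float) -> float:
        return temperature / REFERENCE_T

    def hairpin_energy(self, size: int, temperature: float) -> float:
        if size < self.min_hairpin_loop:
            return _INF
        return self._loop_table(self.hairpin_init, size) * self._scale(temperature)

    def bulge_energy(self, size: int, temperature: float) -> float:
        if size < 1 or size > self.max_internal:
            return _INF
        return self._loop_table(self.bulge_init, size) * self._scale(temperature)

    def internal_energy(self, size: int, temperature: float) -> float:
        if size < 2 or size > self.max_internal:
            return _INF
        return self._loop_table(self.internal_init, size) * self._scale(temperature)

    def multiloop_params(self, temperature: float) -> Tuple[float, float, float]:
        s = self._scale(temperature)
        return (
            self.multiloop_offset * s,
            self.multiloop_branch * s,
            self.multiloop_unpaired * s,
        )

    def penalty_arrays(self, n: int, temperature: float) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Hairpin/bulge/internal penalty vectors indexed by loop size."""
        hp = np.full(n + 1, _INF)
        for size in range(self.min_hairpin_loop, n + 1):
            hp[size] = self.hairpin_energy(size, temperature)
        bulge = np.full(self.max_internal + 1, _INF)
        internal = np.full(self.max_internal + 1, _INF)
        for size in range(1, self.max_internal + 1):
            bulge[size] = self.bulge_energy(size, temperature)
        for size in range(2, self.max_internal + 1):
            internal[size] = self.internal_energy(size, temperature)
        return hp, bulge, internal


DEFAULT_MODEL = EnergyModel()


def celsius_to_kelvin(celsius: float) -> float:
    return celsius + 273.15


def encode_sequence(sequence: str) -> np.ndarray:
    return np.array([_FOLD_INDEX.get(b, 4) for b in sequence.upper()], dtype=np.int8)


def pair_type_matrix(seq_idx: np.ndarray) -> np.ndarray:
    """(n, n) matrix of pair-type indices, -1 where i,j cannot pair."""
    letters = "ACGU"
    n = len(seq_idx)
    pt = np.full((n, n), -1, dtype=np.int8)
    for i in range(n):
        if seq_idx[i] > 3:
            continue
        for j in range(i + 1, n):
            if seq_idx[j] > 3:
                continue
            key = letters[seq_idx[i]] + letters[seq_idx[j]]
            pt[i, j] = _PAIR_INDEX.get(key, -1)
    return pt


@njit(cache=True)
def _fill_dp(pt, stack_e, hp, bulge, internal, ml_a, ml_b, ml_c, min_hp, max_int):
    n = pt.shape[0]
    INF = 1e18
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    for span in range(min_hp + 1, n):
        for i in range(0, n - span):
            j = i + span
            # --- V(i, j): structures closed by pair (i, j)
            if pt[i, j] >= 0:
                best = hp[j - i - 1]
                for k in range(i + 1, j):
                    l1 = k - i - 1
                    if l1 > max_int:
                        break
                    lmin = k + min_hp + 1
                    low = j - 1 - (max_int - l1)
                    if low > lmin:
                        lmin = low
                    for l in range(j - 1, lmin - 1, -1):
                        if pt[k, l] < 0 or V[k, l] >= INF:
                            continue
                        l2 = j - l - 1
                        if l1 == 0 and l2 == 0:
                            cost = stack_e[pt[i, j], pt[k, l]]
                        elif l1 == 0 or l2 == 0:
                            cost = bulge[l1 + l2]
                        else:
                            cost = internal[l1 + l2]
                        total = cost + V[k, l]
                        if total < best:
                            best = total
                for k in range(i + 1, j - 1):
                    if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                        total = ml_a + ml_b + WM[i + 1, k] + WM[k + 1, j - 1]
                        if total < best:
                            best = total
                V[i, j] = best
            # --- WM(i, j): segment inside a multiloop with >= 1 branch
            best = INF
            if WM[i + 1, j] < INF:
                best = WM[i + 1, j] + ml_c
            if WM[i, j - 1] < INF and WM[i, j - 1] + ml_c < best:
                best = WM[i, j - 1] + ml_c
            if V[i, j] < INF and V[i, j] + ml_b < best:
                best = V[i, j] + ml_b
            for k in range(i + 1, j):
                if WM[i, k] < INF and WM[k + 1, j] < INF:
                    total = WM[i, k] + WM[k + 1, j]
                    if total < best:
                        best = total
            WM[i, j] = best
    W = np.zeros(n)
    for j in range(1, n):
        best = W[j - 1]
        for i in range(0, j):
            if V[i, j] < INF:
                left = W[i - 1] if i > 0 else 0.0
                if left + V[i, j] < best:
                    best = left + V[i, j]
        W[j] = best
    return V, WM, W


@dataclass
class FoldResult:
    """A nested secondary structure with its free energy at temperature T."""

    sequence: str
    pair_table: np.ndarray  # partner index, -1 = unpaired
    dG: float  # kcal/mol
    temperature: float  # Kelvin

    @property
    def dot_bracket(self) -> str:
        out = []
        for i, j in enumerate(self.pair_table):
            out.append("." if j < 0 else ("(" if j > i else ")"))
        return "".join(out)


def _unpaired_result(sequence: str, temperature: float) -> FoldResult:
    return FoldResult(
        sequence=sequence,
        pair_table=np.full(len(sequence), -1, dtype=np.int64),
        dG=0.0,
        temperature=temperature,
    )


def fold_mfe(
    sequence: str, temperature: float = 303.15, model: EnergyModel = DEFAULT_MODEL
) -> FoldResult:
    """Minimum-free-energy structure at the given temperature (Kelvin).

    Deterministic: ties are broken by scanning candidate pairings in a
    fixed order (5'-most opening base first) during traceback. Sequences
    too short to fold return the open chain with dG = 0; the open chain
    is always feasible, so dG <= 0.
    """
    n = len(sequence)
    if n < model.min_hairpin_loop + 2:
        return _unpaired_result(sequence, temperature)
    seq_idx = encode_sequence(sequence)
    pt = pair_type_matrix(seq_idx)
    stack_e = model.stack_dh - temperature * model.stack_ds
    hp, bulge, internal = model.penalty_arrays(n, temperature)
    ml_a, ml_b, ml_c = model.multiloop_params(temperature)
    V, WM, W = _fill_dp(
        pt, stack_e, hp, bulge, internal, ml_a, ml_b, ml_c,
        model.min_hairpin_loop, model.max_internal,
    )
    dG = min(0.0, W[n - 1])
    pair_table = np.full(n, -1, dtype=np.int64)
    if dG < 0.0:
        _traceback(
            pt, V, WM, W, stack_e, hp, bulge, internal, ml_a, ml_b, ml_c,
            model.min_hairpin_loop, model.max_internal, pair_table,
        )
    return FoldResult(sequence=sequence, pair_table=pair_table, dG=float(dG), temperature=temperature)


_EPS = 1e-7


def _traceback(pt, V, WM, W, stack_e, hp, bulge, internal, ml_a, ml_b, ml_c,
               min_hp, max_int, pair_table) -> None:
    n = pt.shape[0]
    stack: List[Tuple[str, int, int]] = []
    # exterior loop
    j = n - 1
    while j > 0:
        if W[j] >= (W[j - 1] if j > 0 else 0.0) - _EPS and abs(W[j] - W[j - 1]) <= _EPS:
            j -= 1
            continue
        found = False
        for i in range(0, j):
            left = W[i - 1] if i > 0 else 0.0
            if pt[i, j] >= 0 and abs(left + V[i, j] - W[j]) <= _EPS:
                stack.append(("V", i, j))
                j = i - 1
                found = True
                break
        if not found:  # numerical safety: treat as unpaired
            j -= 1
    while stack:
        kind, i, j = stack.pop()
        if kind == "V":
            pair_table[i] = j
            pair_table[j] = i
            target = V[i, j]
            if abs(hp[j - i - 1] - target) <= _EPS:
                continue
            done = False
            for k in range(i + 1, j):
                l1 = k - i - 1
                if l1 > max_int:
                    break
                for l in range(j - 1, k + min_hp, -1):
                    l2 = j - l - 1
                    if l1 + l2 > max_int or pt[k, l] < 0 or V[k, l] >= _INF:
                        continue
                    if l1 == 0 and l2 == 0:
                        cost = stack_e[pt[i, j], pt[k, l]]
                    elif l1 == 0 or l2 == 0:
                        cost = bulge[l1 + l2]
                    else:
                        cost = internal[l1 + l2]
                    if abs(cost + V[k, l] - target) <= _EPS:
                        stack.append(("V", k, l))
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            for k in range(i + 1, j - 1):
                if WM[i + 1, k] < _INF and WM[k + 1, j - 1] < _INF and abs(
                    ml_a + ml_b + WM[i + 1, k] + WM[k + 1, j - 1] - target
                ) <= _EPS:
                    stack.append(("M", i + 1, k))
                    stack.append(("M", k + 1, j - 1))
                    break
        else:  # WM segment
            target = WM[i, j]
            if target >= _INF:
                continue
            if pt[i, j] >= 0 and abs(V[i, j] + ml_b - target) <= _EPS:
                stack.append(("V", i, j))
            elif i + 1 <= j and WM[i + 1, j] < _INF and abs(WM[i + 1, j] + ml_c - target) <= _EPS:
                stack.append(("M", i + 1, j))
            elif j - 1 >= i and WM[i, j - 1] < _INF and abs(WM[i, j - 1] + ml_c - target) <= _EPS:
                stack.append(("M", i, j - 1))
            else:
                for k in range(i + 1, j):
                    if WM[i, k] < _INF and WM[k + 1, j] < _INF and abs(
                        WM[i, k] + WM[k + 1, j] - target
                    ) <= _EPS:
                        stack.append(("M", i, k))
                        stack.append(("M", k + 1, j))
                        break


# ---------------------------------------------------------------- scoring

class InvalidStructureError(ValueError):
    pass


def structure_energy(
    sequence: str,
    pair_table: Sequence[int],
    temperature: float = 303.15,
    model: EnergyModel = DEFAULT_MODEL,
) -> float:
    """Free energy of a given structure by loop decomposition.

    Independent of the DP: walks the loop tree and sums stack, hairpin,
    bulge/internal and multiloop terms. Structures violating the model
    (non-canonical pair, hairpin < 3, internal loop > cap) score +inf.
    """
    ptab = np.asarray(pair_table, dtype=int)
    n = len(sequence)
    seq_idx = encode_sequence(sequence)
    ptypes = pair_type_matrix(seq_idx)
    for i, j in enumerate(ptab):
        if j >= 0 and ptab[j] != i:
            raise InvalidStructureError("pair table is not an involution")

    def pair_list(lo: int, hi: int) -> List[Tuple[int, int]]:
        """Direct children pairs in the open interval (lo, hi)."""
        out = []
        k = lo
        while k <= hi:
            if ptab[k] > k:
                out.append((k, ptab[k]))
                k = ptab[k] + 1
            elif 0 <= ptab[k] < k:
                raise InvalidStructureError("crossing pairs (pseudoknot)")
            else:
                k += 1
        return out

    stack_e = model.stack_dh - temperature * model.stack_ds
    total = 0.0

    def loop_energy(i: int, j: int) -> float:
        if ptypes[i, j] < 0:
            return _INF
        children = pair_list(i + 1, j - 1)
        if not children:
            return model.hairpin_energy(j - i - 1, temperature)
        if len(children) == 1:
            k, l = children[0]
            l1, l2 = k - i - 1, j - l - 1
            if l1 == 0 and l2 == 0:
                return stack_e[ptypes[i, j], ptypes[k, l]]
            if l1 == 0 or l2 == 0:
                return model.bulge_energy(l1 + l2, temperature)
            return model.internal_energy(l1 + l2, temperature)
        a, b, c = model.multiloop_params(temperature)
        unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
        return a + b * (1 + len(children)) + c * unpaired

    worklist = pair_list(0, n - 1)
    while worklist:
        i, j = worklist.pop()
        e = loop_energy(i, j)
        if e >= _INF:
            return float("inf")
        total += e
        worklist.extend(pair_list(i + 1, j - 1))
    return total


# ------------------------------------------------------- window extraction

def extract_window(
    genome: Genome,
    contig: str,
    position: int,
    flank: int = 400,
    orient_revcomp: Optional[bool] = None,
) -> Tuple[str, int]:
    """Sequence window around a site plus the site's offset inside it.

    The window is clamped at contig bounds. Sites whose reference base is
    T (adenosine on the minus strand) are reverse-complemented to the
    edited-A orientation; pass ``orient_revcomp`` to override.
    """
    if orient_revcomp is None:
        orient_revcomp = genome.base(contig, position) == "T"
    start = max(0, position - flank)
    end = min(genome.length(contig), position + flank + 1)
    window = genome.fetch(contig, start, end)
    offset = position - start
    if orient_revcomp:
        window = revcomp(window)
        offset = len(window) - 1 - offset
    return window, offset


# ----------------------------------------------------------- substructure

@dataclass
class Substructure:
    """The site-containing duplex element of a fold.

    ``fragments`` are (start, end) half-open spans in window coordinates;
    one fragment when the element terminates in a hairpin loop, two arms
    when it abuts a multiloop on the inside.
    """

    verdict: str  # "duplex" or "unpaired"
    fragments: List[Tuple[int, int]] = field(default_factory=list)
    sequences: List[str] = field(default_factory=list)

    @property
    def contiguous(self) -> bool:
        return len(self.fragments) == 1


def _direct_children(ptab: np.ndarray, i: int, j: int) -> List[Tuple[int, int]]:
    out = []
    k = i + 1
    while k < j:
        if ptab[k] > k:
            out.append((k, ptab[k]))
            k = ptab[k] + 1
        else:
            k += 1
    return out


def extract_substructure(fold: FoldResult, site_offset: int) -> Substructure:
    """Duplex element containing the site, or an "unpaired" verdict.

    If the site is paired, the helix run containing it is extended
    through interior loops and bulges until a multiloop or the exterior
    loop; if the site is unpaired inside a hairpin/interior/bulge loop,
    the enclosing helix element is returned; sites in the exterior loop
    or a multiloop are "unpaired".
    """
    ptab = fold.pair_table
    if site_offset < 0 or site_offset >= len(ptab):
        raise ValueError("site offset outside window")
    if ptab[site_offset] >= 0:
        i, j = sorted((site_offset, int(ptab[site_offset])))
        current = (i, j)
    else:
        enclosing = None
        # innermost enclosing pair via a linear scan with a stack
        open_stack: List[int] = []
        for k, partner in enumerate(ptab):
            if k == site_offset:
                enclosing = (open_stack[-1], ptab[open_stack[-1]]) if open_stack else None
                break
            if partner > k:
                open_stack.append(k)
            elif 0 <= partner < k:
                open_stack.pop()
        if enclosing is None:
            return Substructure(verdict="unpaired")
        if len(_direct_children(ptab, *enclosing)) >= 2:
            return Substructure(verdict="unpaired")  # multiloop interior
        current = enclosing

    # outward: follow chains of single-branch loops
    outer = current
    while True:
        i, j = outer
        parent = None
        open_stack = []
        for k, partner in enumerate(ptab):
            if k == i:
                parent = (open_stack[-1], ptab[open_stack[-1]]) if open_stack else None
                break
            if partner > k:
                open_stack.append(k)
            elif 0 <= partner < k:
                open_stack.pop()
        if parent is None or len(_direct_children(ptab, *parent)) != 1:
            break
        outer = parent
    # inward: follow single-branch loops until hairpin or multiloop
    inner = current
    while True:
        children = _direct_children(ptab, *inner)
        if len(children) != 1:
            break
        inner = children[0]
    children = _direct_children(ptab, *inner)
    if len(children) == 0:  # terminates in a hairpin: contiguous element
        frags = [(outer[0], outer[1] + 1)]
    else:  # abuts a multiloop: two arms
        frags = [(outer[0], inner[0] + 1), (inner[1], outer[1] + 1)]
    seqs = [fold.sequence[a:b] for a, b in frags]
    return Substructure(verdict="duplex", fragments=frags, sequences=seqs)


LINKER = "N" * 7


def join_arms(substructure: Substructure) -> str:
    """Single sequence for refolding: arms joined by an unpairable 7-N linker.

    Contiguous substructures are returned unchanged. The alternative
    reading (seven forced N-N pairs) is not implemented; N cannot pair,
    so the linker is inert either way.
    """
    if substructure.verdict != "duplex":
        raise InvalidStructureError("cannot join an unpaired verdict")
    if substructure.contiguous:
        return substructure.sequences[0]
    (a_start, a_end), (b_start, b_end) = substructure.fragments
    if a_end > b_start:
        raise InvalidStructureError("overlapping substructure fragments")
    return substructure.sequences[0] + LINKER + substructure.sequences[1]


def substructure_dG(
    substructure: Substructure,
    temperature: float = 303.15,
    model: EnergyModel = DEFAULT_MODEL,
) -> float:
    """Refold the (possibly linker-joined) substructure and return its dG.

    Sites not located within a double-stranded substructure get dG = 0.
    """
    if substructure.verdict != "duplex":
        return 0.0
    return fold_mfe(join_arms(substructure), temperature, model).dG


def site_stability(
    genome: Genome,
    sites: pd.DataFrame,
    flank: int = 400,
    temperature_c: float = 30.0,
    model: EnergyModel = DEFAULT_MODEL,
    max_window: Optional[int] = None,
) -> pd.DataFrame:
    """Per-site window fold, substructure extraction and dG recompute.

    ``max_window`` truncates the flank for desk-scale runs; temperature
    is supplied in Celsius and converted internally.
    """
    temperature = celsius_to_kelvin(temperature_c)
    effective_flank = flank if max_window is None else min(flank, (max_window - 1) // 2)
    rows = []
    for row in sites.itertuples(index=False):
        window, offset = extract_window(genome, row.contig, row.position, effective_flank)
        fold = fold_mfe(window, temperature, model)
        sub = extract_substructure(fold, offset)
        dg = substructure_dG(sub, temperature, model)
        rows.append(
            {
                "contig": row.contig,
                "position": row.position,
                "window_length": len(window),
                "site_offset": offset,
                "paired": fold.pair_table[offset] >= 0,
                "verdict": sub.verdict,
                "linker_used": sub.verdict == "duplex" and not sub.contiguous,
                "dG": dg,
                "temperature_K": temperature,
            }
        )
    return pd.DataFrame(rows)


def compare_stability(
    dG_sets: Mapping[str, Sequence[float]], include_zeros: bool = True
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U over labelled dG sets.

    Returns one row per pair with medians, U, p and the significance star
    label. Sets with fewer than two values are excluded with a warning;
    ``include_zeros=False`` drops dG == 0 entries (unpaired sites) first.
    """
    cleaned: Dict[str, np.ndarray] = {}
    for label, values in dG_sets.items():
        arr = np.asarray(list(values), dtype=float)
        if not include_zeros:
            arr = arr[arr != 0.0]
        if len(arr) < 2:
            warnings.warn(f"set {label!r} has < 2 values; excluded")
            continue
        cleaned[label] = arr
    labels = list(cleaned)
    rows = []
    for a_idx in range(len(labels)):
        for b_idx in range(a_idx + 1, len(labels)):
            la, lb = labels[a_idx], labels[b_idx]
            xa, xb = cleaned[la], cleaned[lb]
            if np.array_equal(np.sort(xa), np.sort(xb)):
                p = 1.0
            else:
                p = float(mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
            rows.append(
                {
                    "set_a": la,
                    "set_b": lb,
                    "median_a": float(np.median(xa)),
                    "median_b": float(np.median(xb)),
                    "p": p,
                    "stars": star_label(p),
                }
            )
    return pd.DataFrame(rows)
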