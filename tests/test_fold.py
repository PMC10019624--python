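import sys
from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

from editscan.fold import (
    DEFAULT_MODEL,
    REFERENCE_T,
    EnergyModel,
    InvalidStructureError,
    Substructure,
    celsius_to_kelvin,
    compare_stability,
    encode_sequence,
    extract_substructure,
    extract_window,
    fold_mfe,
    join_arms,
    pair_type_matrix,
    site_stability,
    structure_energy,
    substructure_dG,
)
from editscan.genome import Genome
from editscan.stats import star_label

sys.setrecursionlimit(100_000)


# --------------------------------------------------------------- the oracle

def enumerate_structures(seq, model=DEFAULT_MODEL):
    """Yield every valid nested pair set for seq (exhaustive, tiny n only)."""
    pt = pair_type_matrix(encode_sequence(seq))
    minhp = model.min_hairpin_loop

    @lru_cache(maxsize=None)
    def structs(i, j):
        if j - i < minhp + 1:
            return [()]
        out = list(structs(i + 1, j))
        for k in range(i + minhp + 1, j + 1):
            if pt[i, k] >= 0:
                for left in structs(i + 1, k - 1):
                    for right in structs(k + 1, j):
                        out.append(((i, k),) + left + right)
        return out

    return structs(0, len(seq) - 1)


def oracle_mfe(seq, temperature, model=DEFAULT_MODEL):
    """Brute-force MFE: score every structure with the loop-decomposition scorer."""
    best = 0.0
    for pairs in enumerate_structures(seq, model):
        ptab = np.full(len(seq), -1)
        for i, j in pairs:
            ptab[i], ptab[j] = j, i
        energy = structure_energy(seq, ptab, temperature, model)
        best = min(best, energy)
    return best


# -------------------------------------------------------------- energy model

class TestEnergyModel:
    def test_wc_stacks_negative_at_reference_temperature(self):
        model = EnergyModel()
        for outer in range(6):
            for inner in range(6):
                g = model.stack_dh[outer, inner] - REFERENCE_T * model.stack_ds[outer, inner]
                assert g < 0

    def test_hairpin_below_minimum_forbidden(self):
        assert EnergyModel().hairpin_energy(2, 303.15) > 1e17

    def test_loop_penalty_extrapolation_monotone(self):
        model = EnergyModel()
        vals = [model.hairpin_energy(s, 303.15) for s in range(9, 40)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_celsius_conversion(self):
        assert celsius_to_kelvin(30.0) == pytest.approx(303.15)


# ----------------------------------------------------------------- fold_mfe

class TestFoldMfe:
    def test_poly_a_unpaired(self):
        result = fold_mfe("A" * 50)
        assert result.dG == 0.0
        assert (result.pair_table == -1).all()
        assert result.dot_bracket == "." * 50

    def test_too_short_sequence(self):
        result = fold_mfe("GC")
        assert result.dG == 0.0

    def test_gc_hairpin_stronger_than_au(self):
        gc = fold_mfe("GGGGGGAAAACCCCCC")
        au = fold_mfe("AUAUAUAAAAAUAUAU")
        assert gc.dG < au.dG < 0

    def test_n_never_pairs(self):
        result = fold_mfe("GGGGGG" + "N" * 10 + "CCCCCC")
        n_zone = result.pair_table[6:16]
        assert (n_zone == -1).all()

    def test_t_and_u_equivalent(self):
        a = fold_mfe("GGGGGGAAAACCCCCC".replace("U", "T"))
        b = fold_mfe("GGGGGGAAAACCCCCC")
        assert a.dG == b.dG

    def test_dg_never_positive(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            n = int(rng.integers(5, 60))
            seq = "".join(rng.choice(list("ACGU"), n))
            assert fold_mfe(seq).dG <= 0.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(6):
            n = int(rng.integers(12, 23))
            seq = "".join(rng.choice(list("ACGU"), n))
            result = fold_mfe(seq, 303.15)
            assert result.dG == pytest.approx(oracle_mfe(seq, 303.15), abs=1e-6)

    def test_traceback_structure_rescored_equals_dg(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            n = int(rng.integers(15, 45))
            seq = "".join(rng.choice(list("ACGU"), n))
            result = fold_mfe(seq)
            rescored = structure_energy(seq, result.pair_table, 303.15)
            if (result.pair_table >= 0).any():
                assert rescored == pytest.approx(result.dG, abs=1e-6)
            else:
                assert result.dG == 0.0

    def test_deterministic(self):
        seq = "GCAUGGCAUCGGAUCCGGAUGCAUGC"
        a, b = fold_mfe(seq), fold_mfe(seq)
        assert (a.pair_table == b.pair_table).all()
        assert a.dG == b.dG

    def test_pair_table_is_valid_nested(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGU"), 40))
            ptab = fold_mfe(seq).pair_table
            # involution + finite energy implies nestedness via the scorer
            for i, j in enumerate(ptab):
                if j >= 0:
                    assert ptab[j] == i
            if (ptab >= 0).any():
                assert structure_energy(seq, ptab) < np.inf

    def test_helix_extension_never_raises_dg(self):
        core = "GGGAAACCC"
        previous = fold_mfe(core).dG
        seq = core
        for _ in range(4):
            seq = "G" + seq + "C"
            current = fold_mfe(seq).dG
            assert current <= previous + 1e-9
            previous = current


class TestTemperatureDependence:
    def test_fixed_structure_dg_increases_with_temperature(self):
        seq = "GGGGGGGGGGGGAAAACCCCCCCCCCCC"
        structure = fold_mfe(seq, 298.15)
        energies = [
            structure_energy(seq, structure.pair_table, t)
            for t in (288.15, 298.15, 303.15, 310.15, 320.15)
        ]
        assert all(b > a for a, b in zip(energies, energies[1:]))

    def test_mfe_dg_nondecreasing_in_temperature(self):
        rng = np.random.default_rng(53)
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGU"), 50))
            dgs = [fold_mfe(seq, t).dG for t in (283.15, 298.15, 310.15, 330.15)]
            assert all(b >= a - 1e-9 for a, b in zip(dgs, dgs[1:]))

    def test_helix_less_stable_when_warmer(self):
        helix = "G" * 12 + "AAAA" + "C" * 12
        sub = extract_substructure(fold_mfe(helix, 298.15), 3)
        assert substructure_dG(sub, 298.15) < substructure_dG(sub, 307.15)


# ------------------------------------------------------------------- window

class TestExtractWindow:
    def test_full_window_centred(self):
        genome = Genome({"c": "A" * 801})
        window, offset = extract_window(genome, "c", 400, flank=400)
        assert len(window) == 801
        assert offset == 400

    def test_clamped_at_contig_start(self):
        genome = Genome({"c": "A" * 801})
        window, offset = extract_window(genome, "c", 0, flank=400)
        assert len(window) == 401
        assert offset == 0

    def test_minus_strand_revcomp(self):
        genome = Genome({"c": "TTTTGGG"})
        window, offset = extract_window(genome, "c", 3, flank=3)
        assert window == "CCCAAAA"
        assert offset == 3
        assert window[offset] == "A"


# ------------------------------------------------------------- substructure

class TestSubstructure:
    def test_perfect_stem_recovered(self):
        seq = "G" * 20 + "AAAA" + "C" * 20
        fold = fold_mfe(seq)
        sub = extract_substructure(fold, 10)
        assert sub.verdict == "duplex"
        assert sub.contiguous
        start, end = sub.fragments[0]
        assert start == 0 and end == len(seq)

    def test_exterior_site_unpaired_verdict(self):
        seq = "AAAAAA" + "GGGGGG" + "AAAA" + "CCCCCC" + "AAAAAA"
        fold = fold_mfe(seq)
        sub = extract_substructure(fold, 2)  # in the exterior loop
        assert sub.verdict == "unpaired"

    def test_unpaired_site_in_hairpin_loop_gets_enclosing_helix(self):
        seq = "GGGGGG" + "AAAA" + "CCCCCC"
        fold = fold_mfe(seq)
        sub = extract_substructure(fold, 7)  # inside the hairpin loop
        assert sub.verdict == "duplex"

    def test_join_arms_lengths(self):
        sub = Substructure(
            verdict="duplex",
            fragments=[(0, 10), (20, 30)],
            sequences=["G" * 10, "C" * 10],
        )
        joined = join_arms(sub)
        assert len(joined) == 27
        assert joined[10:17] == "NNNNNNN"

    def test_join_contiguous_unchanged(self):
        sub = Substructure(verdict="duplex", fragments=[(0, 12)], sequences=["GGGGAAAACCCC"])
        assert join_arms(sub) == "GGGGAAAACCCC"

    def test_join_overlapping_rejected(self):
        sub = Substructure(
            verdict="duplex", fragments=[(0, 12), (8, 20)], sequences=["A" * 12, "A" * 12]
        )
        with pytest.raises(InvalidStructureError):
            join_arms(sub)

    def test_linker_never_pairs_after_refold(self):
        sub = Substructure(
            verdict="duplex",
            fragments=[(0, 10), (20, 30)],
            sequences=["GGGGGAAAAA", "UUUUUCCCCC"],
        )
        joined = join_arms(sub)
        fold = fold_mfe(joined)
        assert (fold.pair_table[10:17] == -1).all()

    def test_unpaired_verdict_dg_zero(self):
        assert substructure_dG(Substructure(verdict="unpaired")) == 0.0

    def test_substructure_dg_matches_oracle_small_helix(self):
        seq = "GGCGCGCAAAAGCGCGCC"  # 18 nt, foldable, enumerable
        fold = fold_mfe(seq)
        sub = extract_substructure(fold, 4)
        dg = substructure_dG(sub, 303.15)
        assert dg == pytest.approx(oracle_mfe(join_arms(sub), 303.15), abs=1e-6)

    def test_hairpin_planted_sites_mostly_in_duplex(self, hairpin_sim):
        genome, truth = hairpin_sim["genome"], hairpin_sim["truth"]
        hp = truth.records[truth.records["origin"] == "hairpin"]
        in_duplex = 0
        for row in hp.itertuples(index=False):
            window, offset = extract_window(genome, row.contig, row.position, flank=60)
            fold = fold_mfe(window)
            sub = extract_substructure(fold, offset)
            if sub.verdict == "duplex":
                in_duplex += 1
        assert in_duplex / len(hp) >= 0.9


# ------------------------------------------------------------- comparisons

class TestCompareStability:
    def test_identical_sets_ns(self):
        values = list(np.linspace(-10, -1, 30))
        table = compare_stability({"a": values, "b": values})
        assert table.iloc[0]["p"] == 1.0
        assert table.iloc[0]["stars"] == "ns"

    def test_shifted_sets_significant(self):
        rng = np.random.default_rng(19)
        base = rng.normal(-10, 2, 200)
        table = compare_stability({"a": base - 3, "b": base})
        row = table.iloc[0]
        assert row["median_a"] < row["median_b"]
        assert row["p"] <= 0.001
        assert row["stars"] in ("***", "****")

    def test_small_set_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            table = compare_stability({"a": [1.0], "b": [1.0, 2.0, 3.0]})
        assert len(table) == 0

    def test_star_thresholds(self):
        assert star_label(0.03) == "*"
        assert star_label(0.2) == "ns"

    def test_hairpin_vs_background_shift(self, hairpin_sim):
        genome, truth = hairpin_sim["genome"], hairpin_sim["truth"]
        dgs = {"hairpin": [], "background": []}
        for row in truth.records.itertuples(index=False):
            window, offset = extract_window(
                genome, row.contig, row.position, flank=60,
                orient_revcomp=(row.strand == "-"),
            )
            fold = fold_mfe(window)
            sub = extract_substructure(fold, offset)
            dgs[row.origin].append(substructure_dG(sub))
        table = compare_stability(dgs)
        row = table.iloc[0]
        medians = {row["set_a"]: row["median_a"], row["set_b"]: row["median_b"]}
        assert medians["hairpin"] < medians["background"]
        assert row["p"] <= 0.001


class TestSiteStability:
    def test_profile_columns_and_zero_rule(self, hairpin_sim):
        genome, truth = hairpin_sim["genome"], hairpin_sim["truth"]
        sites = truth.records.head(10).rename(columns={"true_level": "level"})
        profile = site_stability(genome, sites, flank=400, temperature_c=30.0, max_window=81)
        assert len(profile) == 10
        assert (profile["window_length"] <= 81).all()
        unpaired = profile[profile["verdict"] == "unpaired"]
        assert (unpaired["dG"] == 0).all()
        assert (profile["dG"] <= 0).all()
        assert profile["temperature_K"].iloc[0] == pytest.approx(303.15)
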