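"""Protocol simulator: mass bookkeeping, stage semantics, MDA size bias."""

import math

import numpy as np
import pytest

from plaskew import simulate as sim
from plaskew.simulate import (
    DEFAULT_EXO_RATE_PER_HOUR,
    NG_PER_BASE,
    MoleculePool,
    Species,
    amplify_mda,
    digest_exonuclease,
    electroelute,
    make_logistic_recovery,
    sample_community,
    shear_and_read,
    to_pool,
)


# --- community construction -------------------------------------------------


def test_sample_community_deterministic_given_seed():
    a = sample_community(50, seed=42)
    b = sample_community(50, seed=42)
    assert [p.sequence for p in a.plasmids] == [p.sequence for p in b.plasmids]
    assert [p.copy_number for p in a.plasmids] == [p.copy_number for p in b.plasmids]
    c = sample_community(50, seed=43)
    assert [p.sequence for p in c.plasmids] != [p.sequence for p in a.plasmids]


def test_sample_community_respects_explicit_sizes(model_mixture_community):
    sizes = [p.length_bp for p in model_mixture_community.plasmids]
    assert sizes == [4400, 56000]
    for p in model_mixture_community.plasmids:
        assert len(p.sequence) == p.length_bp


def test_sample_community_size_range_and_copy_bounds():
    comm = sample_community(40, size_range_bp=(2000, 50000), seed=3)
    for p in comm.plasmids:
        assert 2000 <= p.length_bp <= 50000
        assert 1.0 <= p.copy_number <= 20.0


def test_sample_community_embeds_motif():
    marker = "ATGCGTAAAGGAGAAGAACTTTTCACTGGAGTT"  # gfp 5' fragment
    comm = sample_community(2, sizes=[5000, 9000], motifs={1: marker}, seed=5)
    assert marker in comm.plasmids[1].sequence
    assert marker not in comm.plasmids[0].sequence


def test_sample_community_rejects_bad_inputs():
    with pytest.raises(ValueError):
        sample_community(0)
    with pytest.raises(ValueError):
        sample_community(5, size_range_bp=(5000, 5000))
    with pytest.raises(ValueError):
        sample_community(5, size_range_bp=(100, 10000))
    with pytest.raises(ValueError):
        sample_community(5, gdna_mass_fraction=float("nan"))


# --- pooling ----------------------------------------------------------------


def test_to_pool_equal_mass_molar_ratio(model_mixture_pool):
    """Equal masses of 4.4 and 56 kb plasmids give a 56/4.4 molar ratio."""
    small = model_mixture_pool.get("plasmid_000")
    large = model_mixture_pool.get("plasmid_001")
    assert small.mass_ng == pytest.approx(large.mass_ng)
    assert small.molecules / large.molecules == pytest.approx(56000 / 4400)


def test_to_pool_conserves_total_mass(two_mode_community):
    pool = to_pool(two_mode_community, volume_uL=20.0, conc_ng_per_uL=0.2)
    assert pool.total_mass_ng == pytest.approx(4.0)


def test_to_pool_single_species_gets_all_mass():
    comm = sample_community(1, sizes=[8000], gdna_mass_fraction=0.0, seed=0)
    pool = to_pool(comm, volume_uL=10.0, conc_ng_per_uL=0.3)
    assert pool.get("plasmid_000").mass_ng == pytest.approx(3.0)


def test_to_pool_gdna_share_and_topology():
    comm = sample_community(3, gdna_mass_fraction=0.95, seed=9)
    pool = to_pool(comm)
    gdna = pool.get("gdna")
    assert gdna.topology == "linear"
    assert gdna.mass_ng == pytest.approx(0.95 * pool.total_mass_ng)
    for s in pool.species:
        if s.id != "gdna":
            assert s.topology == "circular"


# --- exonuclease digestion --------------------------------------------------


def test_digest_spares_circular_species(model_mixture_pool):
    digested, _ = digest_exonuclease(model_mixture_pool, hours=96.0)
    for before, after in zip(model_mixture_pool.species, digested.species):
        assert after.molecules == pytest.approx(before.molecules)


def test_digest_zero_hours_is_identity():
    pool = MoleculePool([Species("lin", 10000, "linear", 1e9)])
    out, monitor = digest_exonuclease(pool, hours=0.0)
    assert out.get("lin").molecules == pytest.approx(1e9)
    assert len(monitor) == 1


def test_digest_closed_form_ten_decades():
    """rate = ln(10)/4.8 per hour removes ten decades over 48 h."""
    pool = MoleculePool([Species("lin", 10000, "linear", 1e9)])
    out, monitor = digest_exonuclease(
        pool, hours=48.0, decay_rate_per_hour=math.log(10) / 4.8,
        detection_limit_molecules=1.0,
    )
    assert out.get("lin").molecules == pytest.approx(1e-1, rel=1e-9)
    assert bool(monitor.iloc[-1]["below_detection"])
    assert not bool(monitor.iloc[0]["below_detection"])


def test_digest_default_rate_clears_default_loads():
    """48 h at the default rate drives realistic gDNA loads below 1 molecule."""
    comm = sample_community(5, gdna_mass_fraction=0.95, seed=11)
    pool = to_pool(comm)
    digested, monitor = digest_exonuclease(pool, hours=48.0)
    assert digested.get("gdna").molecules < 1.0
    assert list(monitor["hours"]) == [0.0, 12.0, 24.0, 36.0, 48.0]


def test_digest_never_increases_mass(model_mixture_pool):
    digested, _ = digest_exonuclease(model_mixture_pool, hours=48.0)
    assert digested.total_mass_ng <= model_mixture_pool.total_mass_ng + 1e-12


def test_digest_rejects_negative_rate():
    pool = MoleculePool([Species("lin", 1000, "linear", 1.0)])
    with pytest.raises(ValueError):
        digest_exonuclease(pool, hours=1.0, decay_rate_per_hour=-0.5)


# --- electroelution ---------------------------------------------------------


def test_default_recovery_curve_hits_calibration_points():
    curve = make_logistic_recovery()
    assert curve(56000) == pytest.approx(0.124, rel=1e-9)
    assert curve(4400) == pytest.approx(0.0007, rel=1e-9)
    # monotone increasing in length
    lengths = [1000, 4400, 10000, 23000, 56000, 100000]
    recs = [curve(x) for x in lengths]
    assert recs == sorted(recs)


def test_electroelute_equal_mass_mixture_purity(model_mixture_pool):
    """Measured recoveries leave an eluate that is 99.4 % large plasmid."""
    eluate = electroelute(model_mixture_pool)
    frac = eluate.mass_fractions()["plasmid_001"]
    assert frac == pytest.approx(0.124 / (0.124 + 0.0007), abs=1e-6)
    assert round(100 * frac, 1) == 99.4


def test_electroelute_identity_and_carryover(model_mixture_pool):
    identity = electroelute(model_mixture_pool, recovery_curve=lambda L: 1.0)
    for before, after in zip(model_mixture_pool.species, identity.species):
        assert after.molecules == pytest.approx(before.molecules)
    carry = electroelute(model_mixture_pool, recovery_curve=lambda L: 0.0,
                         carryover=0.01)
    for before, after in zip(model_mixture_pool.species, carry.species):
        assert after.molecules == pytest.approx(0.01 * before.molecules)


def test_electroelute_never_increases_mass(model_mixture_pool):
    eluate = electroelute(model_mixture_pool, carryover=0.5)
    assert eluate.total_mass_ng <= model_mixture_pool.total_mass_ng + 1e-12


def test_electroelute_rejects_bad_recovery(model_mixture_pool):
    with pytest.raises(ValueError):
        electroelute(model_mixture_pool, recovery_curve=lambda L: 1.5)


# --- MDA --------------------------------------------------------------------


def test_mda_zero_budget_is_identity(model_mixture_pool):
    out = amplify_mda(model_mixture_pool, 0.0)
    for before, after in zip(model_mixture_pool.species, out.species):
        assert after.molecules == pytest.approx(before.molecules)


def test_mda_separate_reactions_equal_fold():
    """Identical budget and input mass amplify identically regardless of size."""
    budget = 1e12
    folds = {}
    for length in (4400, 56000):
        mass = 2.0
        pool = MoleculePool([
            Species("p", length, "circular", mass / (length * NG_PER_BASE))
        ])
        out = amplify_mda(pool, budget)
        folds[length] = out.total_mass_ng / pool.total_mass_ng
    assert folds[4400] == pytest.approx(folds[56000], rel=1e-12)


def test_mda_mixed_reaction_molar_advantage(model_mixture_pool):
    """In a mixed equal-mass reaction, synthesized mass splits as L2/L1."""
    out = amplify_mda(model_mixture_pool, 2e14)
    gained = {
        s.id: out.get(s.id).mass_ng - s.mass_ng for s in model_mixture_pool.species
    }
    assert gained["plasmid_000"] / gained["plasmid_001"] == pytest.approx(
        56000 / 4400, rel=1e-9
    )


def test_mda_mass_increases_by_exactly_budget(model_mixture_pool):
    budget = 3.7e13
    out = amplify_mda(model_mixture_pool, budget)
    gained_bases = (out.total_mass_ng - model_mixture_pool.total_mass_ng) / NG_PER_BASE
    assert gained_bases == pytest.approx(budget, rel=1e-9)


def test_mda_no_template_warns_and_passes_through(caplog):
    pool = MoleculePool([Species("lin", 10000, "linear", 1e6)])
    with caplog.at_level("WARNING"):
        out = amplify_mda(pool, 1e12, hours=7.0)
    assert "no amplifiable" in caplog.text
    assert out.get("lin").molecules == pytest.approx(1e6)


def test_mda_background_after_onset(model_mixture_pool):
    """Post-onset incubation diverts the tail of synthesis into background."""
    out = amplify_mda(model_mixture_pool, 1e12, hours=12.0,
                      background_onset_hours=9.0)
    bg = out.get("background")
    assert bg.topology == "linear"
    assert bg.molecules * bg.length_bp == pytest.approx(1e12 * (12 - 9) / 12)
    pre_onset = amplify_mda(model_mixture_pool, 1e12, hours=7.0)
    assert all(s.id != "background" for s in pre_onset.species)


def test_mda_stochastic_matches_deterministic_in_expectation(model_mixture_pool):
    """Multinomial initiation averaged over seeds matches exact allocation."""
    budget = 1e12
    det = amplify_mda(model_mixture_pool, budget, mode="deterministic")
    det_gain = det.get("plasmid_000").mass_ng - model_mixture_pool.get("plasmid_000").mass_ng

    n_seeds = 100
    gains = []
    for seed in range(n_seeds):
        out = amplify_mda(model_mixture_pool, budget, mode="stochastic", seed=seed)
        gains.append(out.get("plasmid_000").mass_ng
                     - model_mixture_pool.get("plasmid_000").mass_ng)
    gains = np.asarray(gains)
    sem = gains.std(ddof=1) / math.sqrt(n_seeds)
    assert abs(gains.mean() - det_gain) < 3 * max(sem, 1e-15)


def test_mda_efficiency_multiplier_shifts_allocation(model_mixture_pool):
    """An efficiency multiplier rescales a species' initiation weight."""
    out = amplify_mda(model_mixture_pool, 2e14,
                      efficiency={"plasmid_001": 56000 / 4400})
    gained = {
        s.id: out.get(s.id).mass_ng - s.mass_ng for s in model_mixture_pool.species
    }
    assert gained["plasmid_000"] == pytest.approx(gained["plasmid_001"], rel=1e-9)


def test_mda_rejects_negative_budget(model_mixture_pool):
    with pytest.raises(ValueError):
        amplify_mda(model_mixture_pool, -1.0)


# --- read generation --------------------------------------------------------


def test_reads_single_species_truth():
    comm = sample_community(1, sizes=[5000], gdna_mass_fraction=0.0, seed=2)
    pool = to_pool(comm)
    rs = shear_and_read(pool, 500, seed=3)
    assert {t.ref_id for t in rs.truth} == {"plasmid_000"}
    assert len(rs.reads) == len(rs.truth) == 500


def test_reads_deterministic_fastq(tmp_path):
    comm = sample_community(3, seed=4)
    pool = to_pool(comm)
    paths = []
    for i in (0, 1):
        rs = shear_and_read(pool, 300, seed=99)
        p = tmp_path / f"r{i}.fastq"
        rs.write_fastq(p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_reads_follow_mass_proportions():
    """Read counts per species land within 3 sd of the binomial expectation."""
    p_small = 0.97
    length = 5000
    n_small = (p_small) / (length * NG_PER_BASE)
    n_large = (1 - p_small) / (length * NG_PER_BASE)
    rng = np.random.default_rng(0)
    pool = MoleculePool([
        Species("a", length, "circular", n_small, sim.random_dna(length, rng)),
        Species("b", length, "circular", n_large, sim.random_dna(length, rng)),
    ])
    n_reads = 10000
    rs = shear_and_read(pool, n_reads, seed=8)
    count_a = sum(1 for t in rs.truth if t.ref_id == "a")
    sd = math.sqrt(n_reads * p_small * (1 - p_small))
    assert abs(count_a - n_reads * p_small) < 3 * sd


def test_reads_wrap_circular_origin():
    rng = np.random.default_rng(1)
    seq = sim.random_dna(200, rng)
    pool = MoleculePool([Species("c", 200, "circular", 1e6, seq)])
    rs = shear_and_read(pool, 2000, read_length_bp=77, seed=5)
    wrapped = [t for t in rs.truth if t.end0 > 200]
    assert wrapped, "with 2000 draws on a 200 bp circle some reads must wrap"
    for t, (rid, read_seq, _q) in zip(rs.truth, rs.reads):
        expected = (seq * 2)[t.start0:t.end0]
        if t.strand == "-":
            expected = sim.reverse_complement(expected)
        assert read_seq == expected


def test_reads_reject_short_linear_sources():
    rng = np.random.default_rng(2)
    pool = MoleculePool([
        Species("short_lin", 50, "linear", 1e9, sim.random_dna(50, rng)),
        Species("circ", 1000, "circular", 1.0, sim.random_dna(1000, rng)),
    ])
    rs = shear_and_read(pool, 100, read_length_bp=77, seed=6)
    assert {t.ref_id for t in rs.truth} == {"circ"}


def test_reads_truth_roundtrip(tmp_path):
    comm = sample_community(2, sizes=[4000, 9000], seed=3,
                            gdna_mass_fraction=0.0)
    pool = to_pool(comm)
    rs = shear_and_read(pool, 200, seed=1, library_label="S")
    path = tmp_path / "truth.tsv"
    rs.write_truth_tsv(path)
    from plaskew.coverage import read_mappings

    loaded = read_mappings(path, library_label="S")
    assert [(r.read_id, r.ref_id, r.start0, r.end0, r.strand) for r in loaded] == [
        (t.read_id, t.ref_id, t.start0, t.end0, t.strand) for t in rs.truth
    ]
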