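"""Alignment, per-CpG calling and conversion QC."""

import numpy as np
import pytest
from scipy.stats import binom

from epiamplicon import (
    MixtureSpec,
    align_to_amplicon,
    call_epiallele,
    call_reads,
    estimate_conversion_efficiency,
    filter_by_conversion,
    simulate_sample_reads,
    simulate_spikein,
)
from epiamplicon.calling import ReadCall

from conftest import clean_mixture


def needleman_wunsch_map(ref, read, match=2, mismatch=-3, gap=-2):
    """Tiny independent global aligner: returns ref->read index map."""
    n, m = len(ref), len(read)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = np.arange(n + 1) * gap
    score[0, :] = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (
                match if ref[i - 1] == read[j - 1] else mismatch
            )
            score[i, j] = max(diag, score[i - 1, j] + gap,
                              score[i, j - 1] + gap)
    mapping = {}
    i, j = n, m
    while i > 0 and j > 0:
        sub = match if ref[i - 1] == read[j - 1] else mismatch
        if score[i, j] == score[i - 1, j - 1] + sub:
            mapping[i - 1] = j - 1
            i, j = i - 1, j - 1
        elif score[i, j] == score[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    return mapping


def test_align_identity_mapping(spec7):
    read = spec7.converted_reference(methylated=True)
    corr = align_to_amplicon(read, spec7)
    assert corr is not None
    assert corr.n_gaps == 0
    assert (corr.ref_to_read == np.arange(len(spec7))).all()
    assert corr.identity == 1.0


def test_align_single_deletion_keeps_cpgs(spec7):
    read = spec7.converted_reference(methylated=True)
    pos = 200
    assert pos not in spec7.cpg_offsets
    deleted = read[:pos] + read[pos + 1 :]
    corr = align_to_amplicon(deleted, spec7)
    assert corr is not None and corr.n_gaps >= 1
    # independent DP oracle on the same (converted-space) pair
    oracle = needleman_wunsch_map(
        spec7.converted_reference(methylated=False),
        deleted.replace("C", "T"),
    )
    for off in spec7.cpg_offsets:
        assert corr.ref_to_read[off] == oracle[off]
    # the call still recovers the fully methylated profile
    call = call_epiallele(corr, spec7)
    assert call.epiallele == "1" * 7


def test_align_rejects_unrelated_sequence(spec7, rng):
    junk = "".join(rng.choice(list("ACGT"), size=len(spec7)))
    # random sequence shares ~25-45% identity in converted space
    assert align_to_amplicon(junk, spec7, min_identity=0.8) is None


def test_call_epiallele_patterns(spec7):
    conv = list(spec7.converted_reference(methylated=False))
    # methylate CpGs 1 and 7 only (TSS-relative -118 and +131)
    for off in (spec7.cpg_offsets[0], spec7.cpg_offsets[-1]):
        conv[off] = "C"
    corr = align_to_amplicon("".join(conv), spec7)
    assert call_epiallele(corr, spec7).epiallele == "1000001"

    all_meth = align_to_amplicon(spec7.converted_reference(True), spec7)
    assert call_epiallele(all_meth, spec7).epiallele == "1" * 7
    all_unmeth = align_to_amplicon(spec7.converted_reference(False), spec7)
    call = call_epiallele(all_unmeth, spec7)
    assert call.epiallele == "0" * 7
    assert call.read_conversion == 1.0


def test_ambiguous_cpg_rejected(spec7):
    conv = list(spec7.converted_reference(methylated=True))
    conv[spec7.cpg_offsets[3]] = "A"
    corr = align_to_amplicon("".join(conv), spec7)
    call = call_epiallele(corr, spec7, max_ambiguous=0)
    assert call.epiallele is None and call.n_ambiguous_cpg == 1


def test_filter_by_conversion_thresholds():
    calls = [
        ReadCall("s", "10", 0, 1.0),
        ReadCall("s", "10", 0, 0.5),
        ReadCall("s", None, 2, 0.0),
    ]
    retained, report = filter_by_conversion(calls)
    assert [c.read_conversion for c in retained] == [1.0]
    assert report == {"retained": 1, "low_conversion": 1, "uncalled": 1}


def test_conversion_filter_matches_binomial_tail(spec7):
    # at 99% conversion, a read fails the 95% screen when more than 5% of
    # its non-CpG Cs stay unconverted: a binomial tail event
    n_reads = 4000
    mix = MixtureSpec(
        {"0" * 7: 1.0}, n_molecules=n_reads, conversion_rate=0.99, seed=11
    )
    _, pairs = simulate_sample_reads(spec7, mix, read_length=len(spec7))
    reads = [f for f, _ in pairs]
    calls = call_reads(reads, spec7)
    _, report = filter_by_conversion(calls, min_read_conversion=0.95)
    n_c = len(spec7.non_cpg_c_offsets)
    cutoff = int(np.ceil(0.95 * n_c))  # converted count below this fails
    p_fail = binom.cdf(cutoff - 1, n_c, 0.99)
    obs = report["low_conversion"] / n_reads
    se = np.sqrt(p_fail * (1 - p_fail) / n_reads)
    assert abs(obs - p_fail) <= 3 * se + 1e-9


def test_roundtrip_error_free(spec7):
    # error-free, fully converted reads reproduce every molecule exactly
    mix = clean_mixture(
        {"1010101": 0.4, "0000000": 0.3, "1111111": 0.3}, 500, seed=21
    )
    molecules, pairs = simulate_sample_reads(spec7, mix)
    from epiamplicon import merge_read_pairs

    merged, n_rej = merge_read_pairs(pairs)
    assert n_rej == 0
    calls = call_reads(merged, spec7)
    assert [c.epiallele for c in calls] == molecules


def test_inappropriate_conversion_monotonicity(spec7):
    # lowering the inappropriate-conversion rate never decreases the
    # called '0' fraction on methylated molecules
    def zero_fraction(rate):
        mix = MixtureSpec(
            {"1" * 7: 1.0}, n_molecules=800,
            inappropriate_conversion_rate=rate, seed=5,
        )
        _, pairs = simulate_sample_reads(spec7, mix, read_length=len(spec7))
        calls = call_reads([f for f, _ in pairs], spec7, max_ambiguous=7)
        bits = "".join(c.epiallele or "" for c in calls)
        return bits.count("0") / max(len(bits), 1)

    fracs = [zero_fraction(r) for r in (0.10, 0.05, 0.0)]
    assert fracs[0] >= fracs[1] >= fracs[2] == 0.0


def test_conversion_estimator_extremes():
    reads, ref = simulate_spikein(50, conversion_rate=1.0, seed=0)
    est = estimate_conversion_efficiency(reads, ref)
    assert est.efficiency == 1.0
    reads, ref = simulate_spikein(50, conversion_rate=0.0, seed=0)
    est = estimate_conversion_efficiency(reads, ref)
    assert est.efficiency == 0.0
    assert est.ci_low <= est.efficiency <= est.ci_high


def test_conversion_estimator_no_reads():
    _, ref = simulate_spikein(1, 1.0, seed=0)
    junk = ["A" * len(ref)] * 3
    est = estimate_conversion_efficiency(junk, ref)
    assert not est.available and est.efficiency is None
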