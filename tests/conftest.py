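"""Shared fixtures and the truth-recovery checker for integration tests."""

from __future__ import annotations

import pytest

from natphase.fixtures import Fixture, FixtureSpec, make_fixture
from natphase.pipeline import RunResult, run
from natphase.seqio import LibraryStats


@pytest.fixture(scope="session")
def fig1b_fixture() -> Fixture:
    """The canonical phased-duplex layout: eight 21-nt sRNAs forming four
    consecutive duplexes with 2-nt 3′ overhangs inside a 120-bp perfectly
    annealed region."""
    return make_fixture(FixtureSpec(seed=1, region_len=120, n_duplex=4, srna_len=21))


def run_fixture(fx: Fixture, **config_kwargs) -> RunResult:
    stats = {
        lib: LibraryStats(lib, tot) for lib, tot in fx.truth.library_totals.items()
    }
    return run(fx.transcripts, fx.srna_reads, fx.degradome_tags, stats, **config_kwargs)


def truth_errors(fx: Fixture, result: RunResult) -> list[str]:
    """Compare a pipeline run against the fixture's ground truth; returns a
    list of human-readable discrepancies (empty = exact recovery)."""
    t = fx.truth
    errs: list[str] = []

    if t.match["score"] >= 60:
        ms = [m for m in result.matches if (m.id_a, m.id_b) == (t.id_a, t.id_b)]
        if len(ms) != 1:
            errs.append(f"expected 1 planted match, found {len(ms)}")
        else:
            m = ms[0]
            for k in (
                "a_start", "a_end", "b_start", "b_end",
                "score", "aln_len", "longest_contig_block",
            ):
                if getattr(m, k) != t.match[k]:
                    errs.append(f"match.{k}: {getattr(m, k)} != {t.match[k]}")
            if abs(m.identity - t.match["identity"]) > 1e-12:
                errs.append("match identity mismatch")

    nats = [n for n in result.nat_pairs if (n.id_a, n.id_b) == (t.id_a, t.id_b)]
    if t.retained:
        if len(nats) != 1:
            errs.append(f"expected 1 retained region, found {len(nats)}")
        else:
            nat = nats[0]
            segs = [(s.a_start, s.a_end, s.b_start, s.b_end) for s in nat.perfect_segments]
            tsegs = [
                (s["a_start"], s["a_end"], s["b_start"], s["b_end"]) for s in t.segments
            ]
            if segs != tsegs:
                errs.append(f"segments: {segs} != {tsegs}")
            bubs = [(b.a_gap_len, b.b_gap_len) for b in nat.duplex.bubbles]
            tbubs = [(b["a_gap_len"], b["b_gap_len"]) for b in t.bubbles]
            if bubs != tbubs:
                errs.append(f"bubbles: {bubs} != {tbubs}")
            if nat.is_cis_candidate != t.is_cis:
                errs.append("cis-candidate flag mismatch")
    elif nats:
        errs.append("region retained although truth says dropped")

    decoys = set(t.decoy_ids)
    if any(m.id_a in decoys or m.id_b in decoys for m in result.matches):
        errs.append("false-positive match on a decoy")
    if any(h.transcript_id in decoys for h in result.mapped_srnas):
        errs.append("read mapped to a decoy")

    if t.cluster:
        if len(result.clusters) != 1:
            errs.append(f"expected 1 cluster, found {len(result.clusters)}")
        else:
            c = result.clusters[0]
            tc = t.cluster
            got = (c.srna_len, c.register, c.n_phases, c.n_srnas)
            exp = (tc["srna_len"], tc["register"], tc["n_phases"], tc["n_srnas"])
            if got != exp:
                errs.append(f"cluster (len, register, phases, srnas): {got} != {exp}")
            if [s.sense_start for s in c.slots] != tc["slot_starts"]:
                errs.append("cluster slot starts mismatch")
        got_ev = {
            (e.transcript_id, e.five_prime_pos, e.slot_index, e.strand, e.tag.id)
            for e in result.evidence
        }
        exp_ev = {
            (e["transcript_id"], e["five_prime_pos"], e["slot_index"], e["strand"], e["tag_id"])
            for e in t.evidence
        }
        if got_ev != exp_ev:
            errs.append(
                f"evidence: unexpected {sorted(got_ev - exp_ev)}, "
                f"missing {sorted(exp_ev - got_ev)}"
            )
    elif result.clusters:
        errs.append("clusters detected although truth expects none")
    return errs
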