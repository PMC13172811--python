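import pytest

from probemine.engine import (FileSummary, ScreenConfig, merge_counts,
                              run_screen, screen_batch)
from probemine.matching import MatchConfig
from probemine.probes import Probe, ProbePanel
from probemine.sampling import SeqRecord
from probemine.simulate import PlantSpec, generate_fixture

from conftest import random_dna


def make_reads(seqs):
    return [SeqRecord(id=f"r{i}", sequence=s) for i, s in enumerate(seqs)]


class TestScreenBatch:
    panel = ProbePanel((Probe.from_sequence("needsG", "GGGG"),))

    def test_impossible_match_by_alphabet(self, rng):
        # {A,T} reads are closed under reverse complement: no G on either strand
        reads = make_reads(random_dna(rng, 30, alphabet="AT") for _ in range(20))
        counts, _, matches = screen_batch(reads, self.panel, MatchConfig(100))
        assert counts == {"needsG": 0} and matches == []

    def test_planted_exact_copies_counted(self, rng):
        reads = make_reads("AC" * 5 + "GGGG" + "CA" * 5 for _ in range(3))
        counts, _, matches = screen_batch(reads, self.panel, MatchConfig(100))
        assert counts == {"needsG": 3}
        assert {m.read_id for m in matches} == {"r0", "r1", "r2"}

    def test_batch_concatenation_is_additive(self, rng):
        reads = make_reads(random_dna(rng, 40) for _ in range(30))
        whole, _, _ = screen_batch(reads, self.panel, MatchConfig(80))
        first, _, _ = screen_batch(reads[:13], self.panel, MatchConfig(80))
        second, _, _ = screen_batch(reads[13:], self.panel, MatchConfig(80))
        assert whole == merge_counts([first, second])

    def test_read_matching_both_strands_counts_once(self):
        panel = ProbePanel((Probe.from_sequence("pal", "ACGT"),))
        counts, _, matches = screen_batch(make_reads(["TTACGTTT"]), panel,
                                          MatchConfig(100))
        assert counts == {"pal": 1} and len(matches) == 1

    def test_multi_probe_read_counts_for_each(self):
        panel = ProbePanel((Probe.from_sequence("a", "AAAA"),
                            Probe.from_sequence("c", "CCCC")))
        counts, _, matches = screen_batch(make_reads(["AAAACCCC"]), panel,
                                          MatchConfig(100))
        assert counts == {"a": 1, "c": 1} and len(matches) == 2

    def test_short_reads_excluded_but_tracked(self):
        panel = ProbePanel((Probe.from_sequence("long", "A" * 20),))
        counts, excluded, _ = screen_batch(make_reads(["ACGTACGT"]), panel,
                                           MatchConfig(100))
        assert counts == {"long": 0} and excluded == {"long": 1}


class TestMergeCounts:
    def test_elementwise_sum(self):
        assert merge_counts([{"p": 2}, {"p": 5}]) == {"p": 7}

    def test_empty_list_is_identity(self):
        assert merge_counts([]) == {}

    def test_order_invariant(self):
        parts = [{"p": 1, "q": 0}, {"p": 4, "q": 2}, {"p": 0, "q": 9}]
        assert merge_counts(parts) == merge_counts(reversed(parts))

    def test_probe_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            merge_counts([{"p": 1}, {"q": 1}])


@pytest.fixture(scope="module")
def planted_fixture(tmp_path_factory):
    """A FASTQ fixture with known planted counts on both strands."""
    panel = ProbePanel((
        Probe.from_sequence("actin", "AGAGATGGCCACGGCTGCTT"),
        Probe.from_sequence("crfk", "CCTGTGAAAAGCCACTCAGA"),
    ))
    path = tmp_path_factory.mktemp("fixture") / "planted.fastq"
    manifest = generate_fixture(
        n_reads=300, read_len=70,
        plant_specs=[PlantSpec(probe=panel["actin"], copies=9),
                     PlantSpec(probe=panel["crfk"], copies=5, strand="-")],
        panel=panel, threshold=100, fmt="fastq", seed=42, out_path=path)
    return path, panel, manifest


class TestRunScreen:
    def test_recovers_manifest_counts(self, planted_fixture):
        path, panel, manifest = planted_fixture
        run = run_screen([path], panel, ScreenConfig(match=MatchConfig(100)))
        (fs,) = run.files
        assert fs.total_selected == 300
        assert fs.counts == manifest.expected_counts(100) == {"actin": 9, "crfk": 5}
        assert fs.error is None

    def test_jobs_and_batch_size_do_not_change_counts(self, planted_fixture):
        path, panel, _ = planted_fixture
        runs = [
            run_screen([path], panel, ScreenConfig(match=MatchConfig(100),
                                                   batch_size=bs, jobs=jobs, seed=5))
            for bs, jobs in [(500, 1), (500, 4), (100, 1), (37, 4)]
        ]
        tables = [(r.files[0].counts, r.files[0].total_selected) for r in runs]
        assert all(t == tables[0] for t in tables)

    def test_match_records_carry_file_tag_and_strand(self, planted_fixture):
        path, panel, manifest = planted_fixture
        run = run_screen([path], panel, ScreenConfig(match=MatchConfig(100)))
        (fs,) = run.files
        by_probe = {}
        for m in fs.matches:
            by_probe.setdefault(m.probe_name, []).append(m)
        assert all(m.file_tag == path.name for m in fs.matches)
        assert {m.strand for m in by_probe["crfk"]} == {"-"}
        assert {m.strand for m in by_probe["actin"]} == {"+"}

    def test_unreadable_file_recorded_not_fatal(self, planted_fixture, tmp_path):
        path, panel, _ = planted_fixture
        missing = tmp_path / "nope.fastq"
        run = run_screen([missing, path], panel, ScreenConfig(match=MatchConfig(100)))
        failed, ok = run.files
        assert failed.error is not None and failed.total_selected == 0
        assert ok.error is None and sum(ok.counts.values()) > 0

    def test_empty_file_yields_zero_summary(self, tmp_path, two_probe_panel):
        empty = tmp_path / "empty.fastq"
        empty.write_text("")
        run = run_screen([empty], two_probe_panel, ScreenConfig())
        (fs,) = run.files
        assert fs.total_selected == 0
        assert all(v == 0 for v in fs.counts.values())
        assert fs.error is None

    def test_subsampled_screen_is_seed_deterministic(self, tmp_path, two_probe_panel):
        # 6,000 reads at ratio 50 -> 5,000 selected (floor above 3,000)
        path = tmp_path / "reads.fastq"
        import random
        r = random.Random(0)
        with open(path, "w") as fh:
            for i in range(6000):
                fh.write(f"@r{i}\n{random_dna(r, 40)}\n+\n{'I' * 40}\n")
        config = ScreenConfig(match=MatchConfig(90), extract_ratio=50, seed=9)
        first = run_screen([path], two_probe_panel, config)
        second = run_screen([path], two_probe_panel, config)
        assert first.files[0].total_selected == 5000
        assert first.files[0].counts == second.files[0].counts

    def test_fasta_subsampling_in_memory(self, tmp_path, two_probe_panel, rng):
        path = tmp_path / "seqs.fasta"
        with open(path, "w") as fh:
            for i in range(200):
                fh.write(f">s{i}\n{random_dna(rng, 60)}\n")
        run = run_screen([path], two_probe_panel,
                         ScreenConfig(extract_ratio=10, seed=4))
        assert run.files[0].total_selected == 20  # no floor for FASTA

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ScreenConfig(batch_size=0)
        with pytest.raises(ValueError):
            ScreenConfig(jobs=0)
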