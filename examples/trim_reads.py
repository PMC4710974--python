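"""Trim 3' sequencing adapters from FASTQ reads and derive insert sizes.

Adapter read-through happens when the insert is shorter than the read; the
trimmer removes the leftmost adapter occurrence (full, or a >= 3-base
prefix at the read end) allowing 10% mismatches.  Insert statistics turn
library metadata into the numbers a spliced aligner asks for.
"""

from tempfile import TemporaryDirectory

from txpipe import FixtureConfig, TrimConfig, insert_stats, make_fixture, trim_fastq

with TemporaryDirectory() as tmp:
    manifest = make_fixture(FixtureConfig(seed=1), tmp)
    sample = sorted(manifest.fastq_by_sample)[0]
    report = trim_fastq(
        manifest.fastq_by_sample[sample],
        f"{tmp}/trimmed.fastq",
        TrimConfig(),  # Illumina universal adapter, 10% error rate
    )
    print(f"sample {sample}: {report.reads_processed} reads, "
          f"{report.reads_trimmed} trimmed, "
          f"mean {report.mean_trimmed_bases:.1f} bases removed per read")

stats = insert_stats(fragment_mean=300, fragment_sd=30, adapter_len=60, read_len=100)
print(f"insert size: {stats.insert_mean:.0f} ± {stats.insert_sd:.0f} bp; "
      f"mate inner distance {stats.mate_inner_distance:.0f} bp")

# A negative inner distance means the two mates of a pair overlap in the
# middle of the insert — common for short libraries and long reads.
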