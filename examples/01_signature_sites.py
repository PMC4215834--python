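"""Call clade signature sites on a small simulated two-clade alignment.

A signature site is a column where one nucleotide is present in >=90% of
the in-group but <=10% of the out-group — a diagnostic substitution of
the clade.  Here three such columns are planted in a 300-column
alignment; the screen recovers exactly those.
"""

from cladescan.alignment_io import filter_gap_columns
from cladescan.conservation import call_signature_sites, site_profiles
from cladescan.simulate import CladeSimConfig, simulate_two_clade_alignment

config = CladeSimConfig(
    n_in=20,
    n_out=20,
    length=300,
    background_rate=0.05,
    planted_signature=[(50, "A", "G"), (120, "C", "U"), (200, "G", "A")],
    gap_rate=0.02,
    seed=7,
)
aln, truth = simulate_two_clade_alignment(config)

filt = filter_gap_columns(aln)
calls = call_signature_sites(site_profiles(filt.filtered, filt.kept_columns))

print(f"alignment: {aln.n_sequences} sequences x {aln.n_columns} columns")
print(f"planted signature columns: {sorted(truth.signature_columns)}")
print("called:")
for c in calls:
    print(
        f"  column {c.column:>4}  {c.nucleotide}  "
        f"in-group {c.freq_in:.2f}  out-group {c.freq_out:.2f}"
    )
# Each line is a clade-diagnostic nucleotide: near-fixed inside the
# clade, nearly absent outside it.
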