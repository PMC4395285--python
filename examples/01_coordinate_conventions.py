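"""Locus strings and the 1-based fully-closed coordinate convention.

Parses published-style location strings, shows that span length equals
end - start + 1, and converts a BED record (0-based, half-open) to the
internal convention without changing the span length.
"""

from telopull import from_bed_record, interval_length, parse_locus_string

# a published telomere-enriched locus, printed with an en-dash
iv = parse_locus_string("chr16:4871450–4874336")
print(f"parsed: {iv.chrom} {iv.start:,}..{iv.end:,}")
print(f"length = end - start + 1 = {interval_length(iv):,} bases")

# the same span as a BED record loses one from the start coordinate
bed = from_bed_record("chr16", 4871449, 4874336)
print(f"from BED (4871449, 4874336): start={bed.start:,}, length={interval_length(bed):,}")

# Both lengths print 2,887 — the closed-convention arithmetic that every
# row of the published locus table satisfies.
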