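"""Build the combined repeat reference and genome mask.

Each repeat family contributes one canonical consensus record plus every
annotated genomic instance extended by F = floor(L/2) = 13 bp of flanking
sequence; the mask partition is the rest of the genome, used by the optional
criterion that discards reads explained as well by un-annotated sequence.
"""

from repeatrain import build_combined_reference, default_config, generate_genome

cfg = default_config(seed=7)
genome, annotation = generate_genome(cfg)
ref = build_combined_reference(annotation, genome, read_length=cfg.read_length)

print(f"read length L = {ref.read_length}, flank F = floor(L/2) = {ref.flank}")
print(f"families: {ref.families}")
print(f"reference records: {len(ref.records)} "
      f"({sum(r.is_canonical for r in ref.records)} canonical, "
      f"{sum(not r.is_canonical for r in ref.records)} flanked instances)")
masked = sum(b - a for _, a, b in ref.mask_partition)
total = sum(len(s) for s in genome.values())
print(f"mask partition: {len(ref.mask_records)} intervals, "
      f"{masked} of {total} bp ({100 * masked / total:.1f}% of the genome "
      f"is not associated with annotated repeat instances)")

rec = next(r for r in ref.records if not r.is_canonical)
print(f"\nexample instance record {rec.record_id}:")
print(f"  extracted (flank-extended) interval: {rec.contig}:{rec.start}-{rec.end}, "
      f"length {len(rec.sequence)} bp")
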