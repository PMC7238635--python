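"""Call CENH3 centromere islands from simulated ChIP coverage.

Simulates input and 8-fold-enriched ChIP coverage over the default
three-chromosome genome, then calls broad enrichment islands with 5-kb
bins, keeping those with summed -log10 Poisson score above 250 and
depth-normalised fold change above 4.  Expect one island per chromosome,
covering each CENH3 domain around its CentC array.
"""
from mapweaver.annotate import call_cenh3_domains, effective_genome_fraction
from mapweaver.simulate import default_config, simulate_chip, simulate_genome

cfg = default_config(seed=2)
genome, truth = simulate_genome(cfg)
chip, inp = simulate_chip(genome, truth.centromeres, cfg)
eff = effective_genome_fraction(genome, k=150)
print(f"effective (unique 150-mer) genome fraction: {eff:.4f}")

islands = call_cenh3_domains(chip, inp, effective_fraction=eff)
print(f"{len(islands)} CENH3 island(s) called "
      f"(truth: {len(truth.centromeres)} centromeres)")
for isl in islands:
    truth_match = next((c for c in truth.centromeres
                        if c.seq_id == isl.seq_id and isl.start < c.end
                        and c.start < isl.end), None)
    tag = "matches truth" if truth_match else "no truth match"
    print(f"  {isl.seq_id}:{isl.start}-{isl.end} score {isl.score:.0f} "
          f"({tag})")
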