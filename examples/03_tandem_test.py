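"""The poly-N tandem-repeat test.

Read mapping can tell whether an element is present in a gap, but not
whether it is present in one copy or two adjacent copies.  Concatenating
two copies with a 50 bp poly-N spacer and mapping pairs against this
artificial reference settles it: only genuinely adjacent copies produce
pairs whose mates fall on opposite sides of the spacer at a valid insert.
"""

from gapbridge import InsertModel, make_fixture, simulate_pairs, tandem_test

fx = make_fixture(seed=42)
im = InsertModel(647, 60)
community = (simulate_pairs(fx.truth.strain1_genome, im, 25, 76, seed=6)
             + simulate_pairs(fx.truth.strain2_genome, im, 25, 76, seed=7))

out = tandem_test(fx.truth.tandem_element, community, im)
print(f"planted tandem element ({len(fx.truth.tandem_element)} bp): "
      f"{out['call']} with {out['spanning_pairs']} spacer-spanning pairs")

calls = [tandem_test(elem, community, im)["call"]
         for elem in fx.truth.dispersed_elements]
print(f"single-copy control elements: {calls.count('single')}/{len(calls)} "
      f"called 'single', {calls.count('tandem')} false positives")
# Spanning pairs exist only for the truly tandem element; dispersed or
# single-copy elements are well covered but produce zero spanning pairs.
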