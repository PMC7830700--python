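"""The state-exclusion filter on a noisy predicted label stream.

Physically impossible adjacent pairs (RF, SE, FR, FE, EF, ES) are
replaced by the previous state; everything else passes through.  The
example corrupts a clean Rest/Extension stream with spurious jumps and
shows the filter repairing them, plus the loop count the sequence
evaluation would report.
"""

from semglove import Motion, SequenceProtocol, apply_state_exclusion, count_loops

noisy = list("RRRRFERRESEEEERRRSRE")  # F after R and S after E are impossible
clean = apply_state_exclusion(noisy)
print("raw     :", "".join(noisy))
print("filtered:", "".join(m.value for m in clean))

protocol = SequenceProtocol((Motion.REST, Motion.EXTENSION))
print("recognized R->E loops in filtered stream:", count_loops(clean, protocol))
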