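# Two-region comparison set: is there a feedback connection 2 -> 1?
models:
  - name: fbk-
    A: [[-1.0, 0.0], [0.5, -1.0]]
    B: [[[0.0, 0.0], [0.0, 0.0]]]
    C: [[1.0], [0.0]]
    free_parameters: [[A, 1, 0], [C, 0, 0]]
  - name: fbk+
    A: [[-1.0, 0.5], [0.5, -1.0]]
    B: [[[0.0, 0.0], [0.0, 0.0]]]
    C: [[1.0], [0.0]]
    free_parameters: [[A, 1, 0], [A, 0, 1], [C, 0, 0]]
model_priors: [0.5, 0.5]
families: {fbk-: without-feedback, fbk+: with-feedback}
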