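level: high
volumes:
- volume: 920.0
  qpoints:
  - q: [0.0, 0.0, 0.0]
    weight: 1.0
    frequencies: [0.0, 0.0, 0.0, 0.5, 1.0580501011420826, 2.2389400330535425, 4.737821456846717,
      10.025704943219596, 21.21539625838834, 44.893904313914305, 95.0]
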