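level: low
volumes:
- volume: 753.48
  qpoints:
  - q: [0.0, 0.0, 0.0]
    weight: 1.0
    frequencies: [0.0, 0.0, 0.0, 0.7001322250122292, 1.4592677034535377, 2.997186585929119,
      6.007522155722295, 11.694224566425154, 22.583793527177704, 45.409091235656064,
      95.31283487043767]
- volume: 795.3400000000001
  qpoints:
  - q: [0.0, 0.0, 0.0]
    weight: 1.0
    frequencies: [0.0, 0.0, 0.0, 0.5890475173430126, 1.2373214229725866, 2.5805401623494353,
      5.31838300565197, 10.805953060809543, 21.87090102613311, 45.14398160870837,
      95.15217081602165]
- volume: 837.2
  qpoints:
  - q: [0.0, 0.0, 0.0]
    weight: 1.0
    frequencies: [0.0, 0.0, 0.0, 0.5, 1.0580501011420826, 2.2389400330535425, 4.737821456846717,
      10.025704943219596, 21.21539625838834, 44.893904313914305, 95.0]
- volume: 879.0600000000001
  qpoints:
  - q: [0.0, 0.0, 0.0]
    weight: 1.0
    frequencies: [0.0, 0.0, 0.0, 0.4278221864023871, 0.911690019007473, 1.9560670080073617,
      4.244510310163566, 9.335877032972439, 20.610121059122054, 44.65731655136388,
      94.85548101047118]
- volume: 920.9200000000001
  qpoints:
  - q: [0.0, 0.0, 0.0]
    weight: 1.0
    frequencies: [0.0, 0.0, 0.0, 0.36872867603142834, 0.7910367777577776, 1.7197064330128145,
      3.8220670119568716, 8.722396986920897, 20.049097735749037, 44.4328981645969,
      94.71789106696417]
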