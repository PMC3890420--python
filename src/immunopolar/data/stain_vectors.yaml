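# Optical-density stain vectors (unit norm, RGB order).
# Published hematoxylin / DAB vectors from the orthonormal color
# deconvolution scheme; override with measured vectors when available.
hematoxylin: [0.650, 0.704, 0.286]
dab: [0.268, 0.570, 0.776]
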