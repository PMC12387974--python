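tissue,n_images,n_correct,n_predicted_to_class
other,155,138,170
slough,302,270,287
necrosis,38,33,37
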