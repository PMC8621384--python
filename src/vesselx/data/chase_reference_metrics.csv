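image_id,sensitivity,specificity,accuracy,precision
retina_01,0.605098,0.969179,0.943788,0.595448
retina_02,0.588396,0.957322,0.923329,0.526972
retina_03,0.670129,0.969808,0.946311,0.653783
retina_04,0.622163,0.978558,0.947489,0.697793
retina_05,0.632404,0.971317,0.943688,0.651083
retina_06,0.582326,0.978046,0.944288,0.66521
retina_07,0.609928,0.968976,0.94101,0.624149
retina_08,0.613154,0.972105,0.947597,0.595198
retina_09,0.600965,0.970603,0.951395,0.567225
retina_10,0.597453,0.963862,0.937151,0.588464
retina_11,0.619103,0.961833,0.940899,0.556381
retina_12,0.592585,0.965196,0.937655,0.564901
retina_13,0.597962,0.973663,0.947481,0.576893
retina_14,0.692803,0.972191,0.95296,0.648084
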