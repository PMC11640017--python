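icd9_code,category_index,category_name
2810.0,1,anemia
2811.1,1,anemia
2812.2,1,anemia
2820.0,2,neutropenia
2821.1,2,neutropenia
2822.2,2,neutropenia
2830.0,3,thrombocytopenia
2831.1,3,thrombocytopenia
2832.2,3,thrombocytopenia
2840.0,4,nausea_vomiting
2841.1,4,nausea_vomiting
2842.2,4,nausea_vomiting
2850.0,5,diarrhea
2851.1,5,diarrhea
2852.2,5,diarrhea
2860.0,6,mucositis
2861.1,6,mucositis
2862.2,6,mucositis
2870.0,7,neuropathy
2871.1,7,neuropathy
2872.2,7,neuropathy
2880.0,8,cardiotoxicity
2881.1,8,cardiotoxicity
2882.2,8,cardiotoxicity
2890.0,9,nephrotoxicity
2891.1,9,nephrotoxicity
2892.2,9,nephrotoxicity
2900.0,10,hepatotoxicity
2901.1,10,hepatotoxicity
2902.2,10,hepatotoxicity
2910.0,11,pulmonary
2911.1,11,pulmonary
2912.2,11,pulmonary
2920.0,12,thromboembolism
2921.1,12,thromboembolism
2922.2,12,thromboembolism
2930.0,13,infection
2931.1,13,infection
2932.2,13,infection
2940.0,14,dehydration
2941.1,14,dehydration
2942.2,14,dehydration
2950.0,15,fatigue
2951.1,15,fatigue
2952.2,15,fatigue
2960.0,16,dermatologic
2961.1,16,dermatologic
2962.2,16,dermatologic
2970.0,17,hypersensitivity
2971.1,17,hypersensitivity
2972.2,17,hypersensitivity
2980.0,18,pain
2981.1,18,pain
2982.2,18,pain
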