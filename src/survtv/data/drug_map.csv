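hcpcs_code,drug_class
J9000,chemotherapy
J9001,chemotherapy
J9002,chemotherapy
J9003,chemotherapy
J9004,chemotherapy
J9005,chemotherapy
J9006,chemotherapy
J9007,chemotherapy
J9008,chemotherapy
J9009,chemotherapy
J9010,chemotherapy
J9011,chemotherapy
J9012,chemotherapy
J9013,chemotherapy
J9014,chemotherapy
J9015,chemotherapy
J9016,chemotherapy
J9017,chemotherapy
J9018,chemotherapy
J9019,chemotherapy
J9020,chemotherapy
J9021,chemotherapy
J9022,chemotherapy
J9023,chemotherapy
J9024,chemotherapy
J9025,chemotherapy
J9026,chemotherapy
J9027,chemotherapy
J9028,chemotherapy
J9029,chemotherapy
J9030,chemotherapy
J9031,chemotherapy
J9032,chemotherapy
J9033,chemotherapy
J9034,chemotherapy
J9035,chemotherapy
J9036,chemotherapy
J9037,chemotherapy
J9038,chemotherapy
J9039,chemotherapy
J9040,chemotherapy
J9041,chemotherapy
J9042,chemotherapy
J9043,chemotherapy
J9044,chemotherapy
J9045,chemotherapy
J9046,chemotherapy
J9047,chemotherapy
J9048,chemotherapy
J9049,chemotherapy
J9050,chemotherapy
J9051,chemotherapy
J9052,chemotherapy
J9053,chemotherapy
J9054,chemotherapy
J9055,chemotherapy
J9056,chemotherapy
J9057,chemotherapy
J9058,chemotherapy
J9059,chemotherapy
J9060,chemotherapy
J9061,chemotherapy
J9062,chemotherapy
J9063,chemotherapy
J9064,chemotherapy
J9065,chemotherapy
J9066,chemotherapy
J9067,chemotherapy
J9068,chemotherapy
J9069,chemotherapy
J9070,chemotherapy
J9071,chemotherapy
J9072,chemotherapy
J9073,chemotherapy
J9074,chemotherapy
J9075,chemotherapy
J9076,chemotherapy
J9077,chemotherapy
J9078,chemotherapy
J9079,chemotherapy
J9080,chemotherapy
J9081,chemotherapy
J8000,biotherapy
J8001,biotherapy
J8002,biotherapy
J8003,biotherapy
J8004,biotherapy
J8005,biotherapy
J8006,biotherapy
J8007,biotherapy
J8008,biotherapy
J8009,biotherapy
J8010,biotherapy
J8011,biotherapy
J8012,biotherapy
J8013,biotherapy
J8014,biotherapy
J8015,biotherapy
J8016,biotherapy
J8017,biotherapy
J8018,biotherapy
J8019,biotherapy
J8020,biotherapy
J8021,biotherapy
J8022,biotherapy
J8023,biotherapy
J8024,biotherapy
J8025,biotherapy
J8026,biotherapy
J8027,biotherapy
J8028,biotherapy
J8029,biotherapy
J8030,biotherapy
J8031,biotherapy
J8032,biotherapy
J8033,biotherapy
J8034,biotherapy
J8035,biotherapy
J8036,biotherapy
J8037,biotherapy
J8038,biotherapy
J8039,biotherapy
J8040,biotherapy
J8041,biotherapy
J8042,biotherapy
J8043,biotherapy
J8044,biotherapy
J8045,biotherapy
J8046,biotherapy
J8047,biotherapy
J8048,biotherapy
J7000,hormone
J7001,hormone
J7002,hormone
J7003,hormone
J7004,hormone
J7005,hormone
J7006,hormone
J7007,hormone
J7008,hormone
J7009,hormone
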